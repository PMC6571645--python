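"""Peptide sequence I/O, validation and dataset curation.

Sequences are restricted to the 20 canonical amino acids; entries carrying
ambiguity codes (X, B, Z, J, O, U) or other special characters are rejected,
mirroring the usual curation step for peptide-activity benchmarks.  Redundancy
reduction uses an internal greedy identity clustering (CD-HIT-like: identity
denominator is the shorter sequence, representatives chosen longest-first) so
no external binary is required.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

ACP = "ACP"
NON_ACP = "nonACP"


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(ValueError):
    """Raised when a sequence fails canonical-alphabet validation."""

    def __init__(self, message: str, offending: str | None = None):
        self.offending = offending
        super().__init__(message)


@dataclass(frozen=True)
class PeptideRecord:
    """A single validated peptide: identifier plus canonical-alphabet sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", validate_peptide(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Peptide records with per-record binary class labels (ACP / nonACP)."""

    records: list[PeptideRecord]
    labels: list[str]

    def __post_init__(self):
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")
        bad = sorted({l for l in self.labels if l not in (ACP, NON_ACP)})
        if bad:
            raise ValueError(f"labels must be '{ACP}' or '{NON_ACP}', got {bad}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in (ACP, NON_ACP)}

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices], [self.labels[i] for i in indices]
        )


def validate_peptide(raw: str) -> str:
    """Uppercase and validate a raw peptide string.

    Only the 20 canonical one-letter codes are accepted.  Ambiguity letters
    (B, J, O, U, X, Z), gap characters, digits and any other symbol raise
    :class:`ValidationError` naming the first offending character.
    """
    if not raw:
        raise ValidationError("empty sequence")
    seq = raw.upper()
    for ch in seq:
        if ch not in _CANONICAL_SET:
            raise ValidationError(
                f"non-canonical character {ch!r} in sequence", offending=ch
            )
    return seq


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read peptides from a FASTA file (wrapped or unwrapped lines).

    The first whitespace-delimited token of each header is the record id.
    Sequences are uppercased and validated.  Order is preserved.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"expected '>' header before sequence data in {path.name}",
                line=lineno,
            )
        break
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaParseError(f"duplicate id {rec.id!r} in {path.name}")
            seen.add(rec.id)
            records.append(PeptideRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA, one sequence line per record."""
    path = Path(path)
    with path.open("w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read an id→label map from a comma- or tab-separated table.

    The file must have a header line ``id,label`` (or tab-separated).
    """
    path = Path(path)
    with path.open(newline="") as handle:
        sample = handle.read(4096)
        handle.seek(0)
        delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(handle, delimiter=delimiter)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames[:2]] != [
            "id",
            "label",
        ]:
            raise ValueError(f"label table {path.name} must have header 'id,label'")
        mapping: dict[str, str] = {}
        for row in reader:
            mapping[row["id"].strip()] = row["label"].strip()
    return mapping


def write_label_table(dataset: LabeledDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        handle.write("id,label\n")
        for rec, lab in zip(dataset.records, dataset.labels):
            handle.write(f"{rec.id},{lab}\n")


def load_dataset(
    fasta: str | Path,
    labels: str | Path | None = None,
    positive_fasta: str | Path | None = None,
    negative_fasta: str | Path | None = None,
) -> LabeledDataset:
    """Assemble a labelled dataset from FASTA plus a label table, or from
    per-class FASTA files (``positive_fasta`` = ACP, ``negative_fasta`` = nonACP)."""
    if positive_fasta is not None or negative_fasta is not None:
        if positive_fasta is None or negative_fasta is None:
            raise ValueError("both per-class FASTA files are required")
        pos = read_fasta(positive_fasta)
        neg = read_fasta(negative_fasta)
        return LabeledDataset(pos + neg, [ACP] * len(pos) + [NON_ACP] * len(neg))
    if labels is None:
        raise ValueError("a label table is required when not using per-class FASTA")
    records = read_fasta(fasta)
    mapping = read_label_table(labels)
    missing = [r.id for r in records if r.id not in mapping]
    if missing:
        raise ValueError(f"records missing from label table: {missing[:5]}")
    return LabeledDataset(records, [mapping[r.id] for r in records])


_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=0.0,
    extend_gap_score=0.0,
)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions between two peptides.

    A global alignment scored match=1 / mismatch=0 / gap=0 is maximized, so the
    optimal score is the largest achievable number of identically aligned
    positions; the identity is that count divided by the length of the shorter
    sequence (the CD-HIT convention).  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    matches = _ALIGNER.score(a, b)
    return matches / min(len(a), len(b))


def redundancy_filter(
    dataset: LabeledDataset, threshold: float = 0.9
) -> LabeledDataset:
    """Greedy within-class redundancy reduction at an identity threshold.

    Within each class, sequences are visited longest-first (ties by input
    order); a sequence joins the first retained representative to which its
    identity exceeds ``threshold``, otherwise it becomes a new representative.
    Only representatives are returned, in original input order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept: set[int] = set()
    for cls in (ACP, NON_ACP):
        idx = [i for i, l in enumerate(dataset.labels) if l == cls]
        order = sorted(idx, key=lambda i: -len(dataset.records[i]))
        reps: list[int] = []
        for i in order:
            seq = dataset.records[i].sequence
            if any(
                pairwise_identity(seq, dataset.records[r].sequence) > threshold
                for r in reps
            ):
                continue
            reps.append(i)
        kept.update(reps)
    keep_sorted = sorted(kept)
    return dataset.subset(keep_sorted)
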