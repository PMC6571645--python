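"""Synthetic two-class peptide generation.

Peptides are drawn with i.i.d. residues from a class-specific composition
(a point on the 20-simplex) and uniformly distributed lengths, which is
enough compositional signal to exercise every descriptor and the full
modelling stack without any positional or secondary-structure realism.
``table5_spec`` reproduces the residue-composition contrast observed between
anticancer and non-anticancer peptides in the curated 138/205 benchmark;
``contrasted_spec`` builds an adjustable-strength contrast around the uniform
composition for calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import ACP, NON_ACP, CANONICAL_AA, LabeledDataset, PeptideRecord
from .sequence_io import write_fasta, write_label_table

# Mean residue composition (%) of the curated anticancer (ACP) and
# non-anticancer peptide classes, in canonical residue order.
TABLE5_ACP_PCT: dict[str, float] = {
    "A": 7.623, "C": 3.906, "D": 2.417, "E": 1.707, "F": 6.823,
    "G": 1.975, "H": 1.536, "I": 10.072, "K": 2.542, "L": 8.099,
    "M": 9.831, "N": 11.497, "P": 0.905, "Q": 5.385, "R": 4.211,
    "S": 6.537, "T": 3.781, "V": 2.258, "W": 2.244, "Y": 6.65,
}
TABLE5_NONACP_PCT: dict[str, float] = {
    "A": 11.005, "C": 8.015, "D": 3.418, "E": 3.523, "F": 2.41,
    "G": 4.123, "H": 5.798, "I": 6.98, "K": 1.651, "L": 3.739,
    "M": 13.888, "N": 3.964, "P": 2.224, "Q": 2.711, "R": 7.495,
    "S": 5.832, "T": 4.704, "V": 1.560, "W": 1.423, "Y": 5.539,
}


@dataclass
class SyntheticSpec:
    """Generator settings: class sizes, length range, class compositions, seed."""

    n_pos: int = 138
    n_neg: int = 205
    length_range: tuple[int, int] = (31, 60)
    pos_composition: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )
    neg_composition: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )
    seed: int = 0

    def __post_init__(self):
        self.pos_composition = _check_simplex(self.pos_composition, "pos_composition")
        self.neg_composition = _check_simplex(self.neg_composition, "neg_composition")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")


def _check_simplex(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (20,):
        raise ValueError(f"{name} must have 20 components")
    if np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-8):
        raise ValueError(f"{name} must be a probability vector over 20 residues")
    return v / v.sum()


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labelled peptide set: lengths ~ Uniform(length_range), residues
    i.i.d. from the class composition.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    residues = np.array(list(CANONICAL_AA))
    records: list[PeptideRecord] = []
    labels: list[str] = []
    for cls, n, comp, prefix in (
        (ACP, spec.n_pos, spec.pos_composition, "acp"),
        (NON_ACP, spec.n_neg, spec.neg_composition, "non"),
    ):
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(residues, size=length, p=comp))
            records.append(PeptideRecord(f"{prefix}{i + 1}", seq))
            labels.append(cls)
    return LabeledDataset(records, labels)


def table5_spec(seed: int = 0, n_pos: int = 138, n_neg: int = 205) -> SyntheticSpec:
    """Generator settings emulating the benchmark's class-composition contrast.

    The class compositions are the published mean residue percentages of the
    ACP and non-ACP classes, divided by 100 and renormalized to sum exactly
    to 1.  Defaults: 138 positives, 205 negatives, lengths 31-60.
    """
    pos = np.array([TABLE5_ACP_PCT[aa] for aa in CANONICAL_AA]) / 100.0
    neg = np.array([TABLE5_NONACP_PCT[aa] for aa in CANONICAL_AA]) / 100.0
    return SyntheticSpec(
        n_pos=n_pos,
        n_neg=n_neg,
        length_range=(31, 60),
        pos_composition=pos / pos.sum(),
        neg_composition=neg / neg.sum(),
        seed=seed,
    )


def contrasted_spec(
    contrast: float = 1.0,
    seed: int = 0,
    n_pos: int = 200,
    n_neg: int = 200,
    length_range: tuple[int, int] = (31, 60),
) -> SyntheticSpec:
    """Two compositions at an adjustable distance from uniform.

    At ``contrast=0`` both classes share the uniform composition; at
    ``contrast=1`` the positive class shifts half its mass toward
    KLFIW-type residues and the negative class toward ADGSE-type residues.
    Intermediate values interpolate linearly, so the inter-class separation
    grows monotonically with ``contrast``.
    """
    if not (0.0 <= contrast <= 1.0):
        raise ValueError("contrast must lie in [0, 1]")
    uniform = np.full(20, 0.05)
    pos_bias = np.array([
        1.0 if aa in "KLFIW" else 0.0 for aa in CANONICAL_AA
    ])
    neg_bias = np.array([
        1.0 if aa in "ADGSE" else 0.0 for aa in CANONICAL_AA
    ])
    pos = (1 - contrast) * uniform + contrast * (
        0.5 * uniform + 0.5 * pos_bias / pos_bias.sum()
    )
    neg = (1 - contrast) * uniform + contrast * (
        0.5 * uniform + 0.5 * neg_bias / neg_bias.sum()
    )
    return SyntheticSpec(
        n_pos=n_pos,
        n_neg=n_neg,
        length_range=length_range,
        pos_composition=pos,
        neg_composition=neg,
        seed=seed,
    )


def write_dataset(dataset: LabeledDataset, fasta: str | Path, labels: str | Path) -> None:
    """Write a generated dataset as FASTA plus an id,label table."""
    write_fasta(dataset.records, fasta)
    write_label_table(dataset, labels)
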