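"""Sequence-derived descriptor encodings for peptides.

Five descriptor families are implemented:

* **AAC** — amino acid composition, the 20 residue frequencies.
* **DPC** — dipeptide composition, the 400 overlapping adjacent-pair
  frequencies.
* **PCP** — physicochemical-property profile: for each property scale, the
  mean standardized property value over the residues of the peptide.
* **PseAAC** — Chou's type-1 pseudo amino acid composition: the 20 residue
  frequencies augmented with λ sequence-order correlation factors θ_j built
  from three standardized base scales (hydrophobicity, hydrophilicity,
  side-chain mass),

      Θ(R_i, R_j) = (1/3) Σ_p (H_p(R_j) − H_p(R_i))²
      θ_j = (1/(L−j)) Σ_{i=1}^{L−j} Θ(R_i, R_{i+j})

  with components f_u/(Σf + w Σθ) for u ≤ 20 and w θ_j/(Σf + w Σθ) for the
  tail, so the vector sums to 1.
* **Am-PseAAC** — the amphiphilic variant: 2λ correlation factors
  τ_{2j−1}, τ_{2j} computed from standardized hydrophobicity (H1) and
  hydrophilicity (H2) separately,

      τ_{2j−1} = (1/(L−j)) Σ_i H1(R_i) H1(R_{i+j}),
      τ_{2j}   = (1/(L−j)) Σ_i H2(R_i) H2(R_{i+j}).

Property scales are standardized to mean 0 / SD 1 (population SD) over the 20
residues before use.  The defaults λ=30, w=0.05 follow common practice for
these descriptors; λ must be strictly smaller than every encoded sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._property_data import (
    AAINDEX_SUBSET,
    PSEAAC_HYDROPHOBICITY,
    PSEAAC_HYDROPHILICITY,
    PSEAAC_SIDECHAIN_MASS,
)
from .sequence_io import CANONICAL_AA, LabeledDataset, PeptideRecord, validate_peptide

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
DIPEPTIDES = ["".join(p) for p in product(CANONICAL_AA, repeat=2)]

ENCODER_NAMES = ("AAC", "DPC", "PCP", "PseAAC", "AmPseAAC")


@dataclass(frozen=True)
class PropertyTable:
    """A named per-residue property scale (AAindex-style)."""

    accession: str
    description: str
    values: Mapping[str, float]

    def __post_init__(self):
        missing = sorted(set(CANONICAL_AA) - set(self.values))
        if missing:
            raise ValueError(
                f"{self.accession}: missing residues {missing}"
            )
        arr = np.array([self.values[aa] for aa in CANONICAL_AA], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{self.accession}: non-finite property values")

    def as_array(self) -> np.ndarray:
        """Values in canonical residue order ACDEFGHIKLMNPQRSTVWY."""
        return np.array([self.values[aa] for aa in CANONICAL_AA], dtype=float)

    def standardized(self) -> np.ndarray:
        """Values standardized to mean 0 / SD 1 (population SD) over the 20 residues."""
        arr = self.as_array()
        sd = arr.std()  # population SD, ddof=0
        if sd == 0:
            raise ValueError(f"{self.accession}: constant scale cannot be standardized")
        return (arr - arr.mean()) / sd


def bundled_property_tables() -> list[PropertyTable]:
    """The bundled AAindex subset (ten informative scales + Hopp-Woods)."""
    return [
        PropertyTable(acc, desc, vals) for acc, (desc, vals) in AAINDEX_SUBSET.items()
    ]


def read_aaindex1(path: str | Path) -> list[PropertyTable]:
    """Parse property scales from an AAindex1 flat file (H/D/I record lines).

    Entries with any NA value are skipped, mirroring the usual curation of the
    531 usable scales out of 544.
    """
    tables: list[PropertyTable] = []
    accession = description = None
    lines = Path(path).read_text().splitlines()
    i = 0
    # residue order of the two AAindex1 I-record value rows
    row1 = "ARNDCQEGHI"
    row2 = "LKMFPSTWYV"
    while i < len(lines):
        line = lines[i]
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("D "):
            description = line[2:].strip()
        elif line.startswith("I "):
            vals1 = lines[i + 1].split()
            vals2 = lines[i + 2].split()
            i += 2
            if accession is None:
                raise ValueError("I record before H record in AAindex1 file")
            if "NA" in vals1 or "NA" in vals2:
                accession = description = None
            else:
                values = {aa: float(v) for aa, v in zip(row1, vals1)}
                values.update({aa: float(v) for aa, v in zip(row2, vals2)})
                tables.append(PropertyTable(accession, description or "", values))
                accession = description = None
        i += 1
    return tables


# standardized base scales used by PseAAC / Am-PseAAC, in canonical order
def _standardized(scale: Mapping[str, float]) -> np.ndarray:
    arr = np.array([scale[aa] for aa in CANONICAL_AA], dtype=float)
    return (arr - arr.mean()) / arr.std()


_H1 = _standardized(PSEAAC_HYDROPHOBICITY)
_H2 = _standardized(PSEAAC_HYDROPHILICITY)
_H3 = _standardized(PSEAAC_SIDECHAIN_MASS)


def _indices(seq: str) -> np.ndarray:
    seq = validate_peptide(seq)
    return np.array([_AA_INDEX[aa] for aa in seq], dtype=np.intp)


def encode_aac(seq: str) -> np.ndarray:
    """Amino acid composition: 20 residue frequencies, summing to 1."""
    idx = _indices(seq)
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / len(idx)


def encode_dpc(seq: str) -> np.ndarray:
    """Dipeptide composition: 400 overlapping-pair frequencies, summing to 1."""
    idx = _indices(seq)
    if len(idx) < 2:
        raise ValueError("DPC requires sequence length >= 2")
    pair_codes = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pair_codes, minlength=400).astype(float)
    return counts / (len(idx) - 1)


def encode_pcp(seq: str, tables: Sequence[PropertyTable]) -> np.ndarray:
    """Physicochemical profile: per scale, the mean standardized value over residues."""
    if not tables:
        raise ValueError("encode_pcp requires at least one property table")
    idx = _indices(seq)
    return np.array([t.standardized()[idx].mean() for t in tables])


def _correlation_factors_theta(idx: np.ndarray, lam: int) -> np.ndarray:
    """Type-1 sequence-order factors θ_1..θ_λ."""
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        a, b = idx[:-j], idx[j:]
        theta = (
            (_H1[b] - _H1[a]) ** 2 + (_H2[b] - _H2[a]) ** 2 + (_H3[b] - _H3[a]) ** 2
        ) / 3.0
        thetas[j - 1] = theta.mean()
    return thetas


def encode_paac(seq: str, lambda_: int = 30, weight: float = 0.05) -> np.ndarray:
    """Chou's type-1 pseudo amino acid composition, a (20+λ)-vector summing to 1."""
    _check_pse_params(lambda_, weight)
    idx = _indices(seq)
    if len(idx) <= lambda_:
        raise ValueError(
            f"sequence length {len(idx)} must exceed lambda={lambda_} for PseAAC"
        )
    freqs = np.bincount(idx, minlength=20) / len(idx)
    thetas = _correlation_factors_theta(idx, lambda_) if lambda_ else np.empty(0)
    denom = freqs.sum() + weight * thetas.sum()
    return np.concatenate([freqs, weight * thetas]) / denom


def encode_apaac(seq: str, lambda_: int = 30, weight: float = 0.05) -> np.ndarray:
    """Amphiphilic pseudo amino acid composition, a (20+2λ)-vector."""
    _check_pse_params(lambda_, weight)
    idx = _indices(seq)
    if len(idx) <= lambda_:
        raise ValueError(
            f"sequence length {len(idx)} must exceed lambda={lambda_} for Am-PseAAC"
        )
    freqs = np.bincount(idx, minlength=20) / len(idx)
    taus = np.empty(2 * lambda_)
    for j in range(1, lambda_ + 1):
        a, b = idx[:-j], idx[j:]
        taus[2 * j - 2] = (_H1[a] * _H1[b]).mean()
        taus[2 * j - 1] = (_H2[a] * _H2[b]).mean()
    denom = freqs.sum() + weight * taus.sum()
    return np.concatenate([freqs, weight * taus]) / denom


def _check_pse_params(lambda_: int, weight: float) -> None:
    if lambda_ < 0 or int(lambda_) != lambda_:
        raise ValueError(f"lambda must be a non-negative integer, got {lambda_}")
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")


@dataclass
class EncoderConfig:
    """Which encoders to apply, in order, and their shared parameters."""

    encoders: tuple[str, ...] = ("AAC",)
    lambda_: int = 30
    weight: float = 0.05
    pcp_tables: list[PropertyTable] = field(default_factory=bundled_property_tables)

    def __post_init__(self):
        self.encoders = tuple(self.encoders)
        if not self.encoders:
            raise ValueError("at least one encoder is required")
        unknown = [e for e in self.encoders if e not in ENCODER_NAMES]
        if unknown:
            raise ValueError(f"unknown encoders {unknown}; valid: {ENCODER_NAMES}")
        _check_pse_params(self.lambda_, self.weight)

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for enc in self.encoders:
            if enc == "AAC":
                names += [f"AAC:{aa}" for aa in CANONICAL_AA]
            elif enc == "DPC":
                names += [f"DPC:{dp}" for dp in DIPEPTIDES]
            elif enc == "PCP":
                names += [f"PCP:{t.accession}" for t in self.pcp_tables]
            elif enc == "PseAAC":
                names += [f"PAAC:{aa}" for aa in CANONICAL_AA]
                names += [f"PAAC:theta{j}" for j in range(1, self.lambda_ + 1)]
            elif enc == "AmPseAAC":
                names += [f"APAAC:{aa}" for aa in CANONICAL_AA]
                names += [f"APAAC:tau{k}" for k in range(1, 2 * self.lambda_ + 1)]
        return names

    def encode_sequence(self, seq: str) -> np.ndarray:
        parts = []
        for enc in self.encoders:
            if enc == "AAC":
                parts.append(encode_aac(seq))
            elif enc == "DPC":
                parts.append(encode_dpc(seq))
            elif enc == "PCP":
                parts.append(encode_pcp(seq, self.pcp_tables))
            elif enc == "PseAAC":
                parts.append(encode_paac(seq, self.lambda_, self.weight))
            elif enc == "AmPseAAC":
                parts.append(encode_apaac(seq, self.lambda_, self.weight))
        return np.concatenate(parts)


class PeptideEncoder(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer turning peptide sequences into a feature matrix.

    Parameters mirror :class:`EncoderConfig`; ``transform`` accepts a list of
    sequences, a list of :class:`PeptideRecord` or a :class:`LabeledDataset`
    and returns a :class:`pandas.DataFrame` indexed by sample id with
    namespaced descriptor columns (``AAC:K``, ``DPC:KK``, ``PAAC:theta1``, …).
    """

    def __init__(self, encoders=("AAC",), lambda_=30, weight=0.05, pcp_tables=None):
        self.encoders = encoders
        self.lambda_ = lambda_
        self.weight = weight
        self.pcp_tables = pcp_tables

    def _config(self) -> EncoderConfig:
        kwargs = dict(
            encoders=tuple(self.encoders), lambda_=self.lambda_, weight=self.weight
        )
        if self.pcp_tables is not None:
            kwargs["pcp_tables"] = list(self.pcp_tables)
        return EncoderConfig(**kwargs)

    def fit(self, X, y=None):
        config = self._config()
        self.config_ = config
        self.feature_names_out_ = config.feature_names()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit(X)
        ids, seqs = _as_ids_sequences(X)
        rows = np.empty((len(seqs), len(self.feature_names_out_)))
        for i, (sid, seq) in enumerate(zip(ids, seqs)):
            try:
                rows[i] = self.config_.encode_sequence(seq)
            except ValueError as exc:
                raise ValueError(f"cannot encode sequence {sid!r}: {exc}") from exc
        return pd.DataFrame(rows, index=pd.Index(ids, name="id"),
                            columns=self.feature_names_out_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)


def _as_ids_sequences(X) -> tuple[list[str], list[str]]:
    if isinstance(X, LabeledDataset):
        return X.ids, X.sequences
    ids, seqs = [], []
    for i, item in enumerate(X):
        if isinstance(item, PeptideRecord):
            ids.append(item.id)
            seqs.append(item.sequence)
        else:
            ids.append(f"s{i + 1}")
            seqs.append(str(item))
    return ids, seqs


def encode_dataset(dataset, config: EncoderConfig | None = None) -> pd.DataFrame:
    """Encode a dataset (or sequence list) into a feature matrix DataFrame."""
    config = config or EncoderConfig()
    enc = PeptideEncoder(
        encoders=config.encoders,
        lambda_=config.lambda_,
        weight=config.weight,
        pcp_tables=config.pcp_tables,
    )
    return enc.fit(None).transform(dataset)


def write_feature_matrix(X: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix as CSV (first column = sample id)."""
    X.to_csv(path, index_label="id")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
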