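import numpy as np
import pytest

from acpkit import (
    EncoderConfig,
    LabeledDataset,
    PeptideRecord,
    encode_dataset,
    generate_dataset,
    table5_spec,
)
from acpkit.sequence_io import ACP, CANONICAL_AA, NON_ACP


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    """60 peptides, 30 per class, compositionally contrasted classes."""
    ds = generate_dataset(table5_spec(seed=7, n_pos=30, n_neg=30))
    return ds


@pytest.fixture
def separable_xy(rng):
    """Linearly separable 2-D points, 20 per class."""
    import pandas as pd

    pos = rng.normal([4.0, 4.0], 0.3, size=(20, 2))
    neg = rng.normal([-4.0, -4.0], 0.3, size=(20, 2))
    X = pd.DataFrame(np.vstack([pos, neg]), columns=["f1", "f2"])
    y = np.array([ACP] * 20 + [NON_ACP] * 20)
    return X, y


@pytest.fixture
def tiny_records():
    return [
        PeptideRecord("p1", "KWKLFKKIEK"),
        PeptideRecord("p2", "GIGAVLKVLT"),
        PeptideRecord("p3", "ACDEFGHIKL"),
    ]
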