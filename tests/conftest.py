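import numpy as np
import pytest

from amylstm import ProteinRecord, SynthConfig, generate


@pytest.fixture
def tiny_records():
    """Four short canonical records, two per class."""
    return [
        ProteinRecord("p1", "MKVACDE", label=1),
        ProteinRecord("p2", "QNNQQNYA", label=1),
        ProteinRecord("n1", "GGSTRRK", label=0),
        ProteinRecord("n2", "ACDEFGHIKL", label=0),
    ]


@pytest.fixture
def small_dataset():
    """80 synthetic sequences with a fully planted motif (seeded)."""
    return generate(SynthConfig(
        n_pos=40, n_neg=40, length_range=(20, 60), motif_prob=1.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
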