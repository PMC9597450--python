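import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def six_genotypes():
    return ["G1", "G2", "G3", "G4", "G5", "G6"]


@pytest.fixture
def small_matrix(six_genotypes):
    """14-band, 6-genotype matrix with a known mix of band classes."""
    from sesamediv.band_matrix import BandMatrix, BandRecord

    patterns = [
        ("P1", (1, 1, 1, 1, 1, 1)),  # monomorphic
        ("P1", (0, 0, 0, 1, 0, 0)),  # unique positive
        ("P1", (1, 1, 0, 1, 1, 1)),  # unique negative
        ("P1", (1, 1, 0, 0, 1, 0)),  # other polymorphic
        ("P1", (1, 0, 1, 0, 1, 0)),
        ("P1", (1, 1, 1, 1, 1, 1)),
        ("P2", (1, 1, 1, 1, 1, 1)),
        ("P2", (0, 1, 0, 0, 0, 0)),
        ("P2", (0, 0, 1, 1, 0, 0)),
        ("P2", (1, 1, 1, 0, 1, 1)),
        ("P2", (0, 1, 1, 1, 1, 0)),
        ("P2", (1, 0, 0, 1, 1, 0)),
        ("P2", (1, 1, 0, 1, 0, 1)),
        ("P2", (0, 0, 0, 0, 1, 0)),
    ]
    records = [
        BandRecord(assay_id=a, band_id=f"b{i}", fragment_size=1500 - 50 * i, presence=p)
        for i, (a, p) in enumerate(patterns)
    ]
    return BandMatrix(list(six_genotypes), records)
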