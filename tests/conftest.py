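import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssrfp import (
    BinaryGenotypeMatrix,
    LocusDefinition,
    SampleRecord,
    SimulationConfig,
    simulate_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_matrix(rows, loci, ploidy=6, groups=None):
    """Build a matrix from a list of per-sample call lists."""
    samples = [
        SampleRecord(f"S{i + 1}", (groups or {}).get(i, "study"))
        for i in range(len(rows))
    ]
    return BinaryGenotypeMatrix(samples, loci, np.asarray(rows, dtype=np.int8), ploidy)


@pytest.fixture
def two_locus_matrix():
    """4 samples x 2 loci (3 + 2 alleles), complete data."""
    loci = [LocusDefinition("LA", (100, 102, 104)), LocusDefinition("LB", (200, 204))]
    rows = [
        [1, 1, 0, 1, 0],
        [1, 1, 0, 1, 0],
        [1, 0, 1, 0, 1],
        [0, 1, 1, 1, 1],
    ]
    return make_matrix(rows, loci)


@pytest.fixture(scope="session")
def clone_dataset():
    """Default-condition synthetic clone dataset (19 loci, noise on)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def clean_clone_dataset():
    """Noise-free clone dataset: within-clone distances are exactly zero."""
    cfg = SimulationConfig(
        seed=7, dropout_rate=0.0, false_allele_rate=0.0, locus_missing_rate=0.0
    )
    return simulate_dataset(cfg)
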