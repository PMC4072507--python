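"""Shared fixtures: toy assemblies and one session-scoped synthetic dataset."""

import numpy as np
import pytest

from enhancerscan import FeatureTrack, GenomeAssembly, GenomicInterval, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default-configuration synthetic dataset; shared by heavy tests."""
    return generate_dataset(SimConfig(seed=2026))


@pytest.fixture(scope="session")
def small_dataset():
    """A smaller synthetic dataset for fast smoke/CLI tests."""
    return generate_dataset(
        SimConfig(seed=11, n_chroms=2, chrom_length=300_000, n_enhancers=60, n_negatives=60)
    )


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seqs = {
        "chr1": "".join(bases[rng.integers(0, 4, size=50_000)]),
        "chr2": "".join(bases[rng.integers(0, 4, size=30_000)]),
    }
    return GenomeAssembly(sequences=seqs)


@pytest.fixture()
def toy_track():
    return FeatureTrack(
        "peaks",
        [
            GenomicInterval("chr1", 150, 300),
            GenomicInterval("chr1", 1000, 1400),
            GenomicInterval("chr2", 50, 120),
        ],
    )
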