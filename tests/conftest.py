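import numpy as np
import pandas as pd
import pytest

from embryocn import CoverageModel, toy_genome
from embryocn.config import GenomeConfig


@pytest.fixture(scope="session")
def genome():
    """Default 3-chromosome desk-scale genome."""
    return toy_genome(seed=0)


@pytest.fixture(scope="session")
def genome6():
    """Mouse-like genome with more, smaller chromosomes so that a
    whole-chromosome imbalance stays a small fraction of the genome."""
    return toy_genome(
        chrom_lengths=(30_000_000, 28_000_000, 26_000_000,
                       24_000_000, 22_000_000, 20_000_000),
        snp_spacing=10_000,
        seed=0,
    )


@pytest.fixture(scope="session")
def genome6_config():
    return GenomeConfig(
        n_chromosomes=6,
        chrom_lengths=[30_000_000, 28_000_000, 26_000_000,
                       24_000_000, 22_000_000, 20_000_000],
        snp_spacing=10_000,
    )


@pytest.fixture
def deep():
    return CoverageModel(mean_depth=9.45, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_bin_counts(values_by_sample, bin_size=10_000, chrom="chr1"):
    """Small BinCountMatrix literal for unit tests."""
    from embryocn.depth import BinCountMatrix

    n = len(next(iter(values_by_sample.values())))
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * bin_size,
            "end": (np.arange(n) + 1) * bin_size,
        }
    )
    counts = pd.DataFrame({k: np.asarray(v) for k, v in values_by_sample.items()})
    return BinCountMatrix(bins=bins, counts=counts, bin_size=bin_size)
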