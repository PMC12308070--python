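import numpy as np
import pandas as pd
import pytest

from cfepiscan import simulate


@pytest.fixture(scope="session")
def genome():
    return simulate.generate_genome(101, n_chrom=2, lengths=(600_000, 400_000))


@pytest.fixture(scope="session")
def cohort_small():
    return simulate.generate_cohort(102, n_hc=12, n_scz=10, n_imaging_hc=10, n_imaging_scz=8)


@pytest.fixture(scope="session")
def cohort_full():
    return simulate.generate_cohort(103)


@pytest.fixture(scope="session")
def counts_small(genome, cohort_small):
    counts, truth = simulate.generate_counts(genome, cohort_small, 104, n_true=10)
    return counts, truth


def make_regions(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
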