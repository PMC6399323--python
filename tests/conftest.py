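import numpy as np
import pytest
from hypothesis import settings

from ccinfarct import haplotype, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_panel():
    return simulate.simulate_founders(n_snps_per_chrom=80, n_chroms=2, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    genomes = simulate.simulate_cc_panel(
        small_panel, n_strains=40, expected_breakpoints_per_chrom=3.0,
        genotype_error_rate=0.002, seed=102,
    )
    return genomes


@pytest.fixture(scope="session")
def small_dosages(small_panel, small_cohort):
    probs = haplotype.infer_cohort(small_cohort, small_panel)
    return haplotype.stack_dosages(probs)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
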