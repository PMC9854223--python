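import numpy as np
import pytest

import radiomethyl as rm
from radiomethyl.dream import DreamConfig


@pytest.fixture(scope="session")
def small_genome():
    return rm.generate_genome(
        n_contigs=1, contig_length=50_000, n_sites=20, n_islands=2,
        n_tss=5, n_repeats=1, seed=7,
    )


@pytest.fixture(scope="session")
def catalog(small_genome):
    return small_genome.site_flanks()


@pytest.fixture(scope="session")
def planted_truth(small_genome, catalog):
    diff_sites = list(catalog["site_id"][:5])
    return rm.plant_differential_truth(
        small_genome, n_per_group=8, differential_sites=diff_sites,
        fraction_a=0.20, fraction_b=0.40, seed=3,
    ), diff_sites


@pytest.fixture(scope="session")
def profiled(small_genome, catalog, planted_truth):
    truth, diff_sites = planted_truth
    tags = rm.generate_dream_tags(small_genome, truth, depth=200, seed=5)
    profiles, qc = rm.profile_sites(tags, catalog, DreamConfig())
    return profiles, qc, truth, diff_sites


def rng(seed=0):
    return np.random.default_rng(seed)
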