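"""Shared fixtures: small maps, populations and breeding configurations."""

import numpy as np
import pytest

from wffsim import breeding_engine as be
from wffsim import founder_genomes as fg
from wffsim import trait_model as tm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    """Two chromosomes of 50 cM with 2 QTL + 20 neutral loci each."""
    return fg.build_genetic_map(n_chromosomes=2, chrom_length=50, n_qtl=2, n_neutral=20, seed=7)


@pytest.fixture
def small_pop(small_map):
    return fg.sample_founder_haplotypes(small_map, n_founders=200, spectrum="neutral", seed=7)


@pytest.fixture
def small_config():
    """Scaled-down breeding scheme: 20 sires, 50 offspring, deciles of 2."""
    return be.BreedingConfig(
        n_male_candidates=25,
        n_dams=25,
        n_sires=20,
        split=(8, 12),
        n_offspring=50,
        decile_counts=(1, 1, 1, 1, 2, 2, 3, 3, 4, 7),
    )


def make_cohort(haplotypes, arch, model, generation=0, seed=0, lethal_locus=0):
    """Assemble a cohort from raw haplotypes with computed values/statuses."""
    from wffsim.lethal_allele import classify_carriers

    rng = np.random.default_rng(seed)
    n = haplotypes.shape[0]
    sex = np.empty(n, dtype=np.int8)
    sex[: n // 2] = be.MALE
    sex[n // 2 :] = be.FEMALE
    sex = sex[rng.permutation(n)]
    gv = tm.genetic_values(haplotypes, arch)
    return be.Cohort(
        generation=generation,
        ids=np.arange(n, dtype=np.int64) + generation * 1_000_000,
        sex=sex,
        haplotypes=haplotypes,
        genetic_value=gv,
        phenotype=tm.phenotypes(gv, model, rng),
        status=classify_carriers(haplotypes, lethal_locus),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
    )
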