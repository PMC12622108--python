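import numpy as np
import pytest

from admixprs.harmonize import harmonize
from admixprs.pipeline import cohort_covariates
from admixprs.simulate import (
    AncestryModel,
    PhenotypeModel,
    default_variant_map,
    emulate_gwas,
    generate_cohort,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample, 200-variant five-way admixed cohort with 30 causal SNPs."""
    vmap = default_variant_map(200, n_chroms=2)
    cohort = generate_cohort(AncestryModel(), 300, vmap, seed=11)
    rng = np.random.default_rng(7)
    betas = np.zeros(200)
    idx = rng.choice(200, size=30, replace=False)
    betas[idx] = rng.choice([-0.25, 0.25], size=30)
    model = PhenotypeModel(true_betas=betas, ancestry_effects={"AFR": 0.3})
    cohort = simulate_phenotype(cohort, model, seed=12)
    freqs = np.clip(cohort.alleles.mean(axis=(0, 1)), 1e-3, 1 - 1e-3)
    sumstats = emulate_gwas(betas, freqs, cohort.variants, base_n=50_000, seed=13)
    return cohort, sumstats


@pytest.fixture(scope="session")
def small_harmonized(small_cohort):
    cohort, sumstats = small_cohort
    return harmonize(sumstats, cohort.variants)


@pytest.fixture(scope="session")
def small_covariates(small_cohort):
    cohort, _ = small_cohort
    cov, anc_cols = cohort_covariates(cohort)
    return cov, anc_cols
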