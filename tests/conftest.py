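import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gazeprs.genetics import GenotypeData
from gazeprs.simulate import CohortConfig, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes() -> GenotypeData:
    """Clean 200-subject x 40-variant genotype panel (no missingness)."""
    return simulate_genotypes(
        CohortConfig(n_subjects=200, n_snps=40, maf_range=(0.1, 0.5), seed=7)
    )


def make_genotypes(dosages: np.ndarray, effect="A", other="G") -> GenotypeData:
    """Wrap a raw dosage array in a GenotypeData with stub variant info."""
    n_sub, n_var = dosages.shape
    ids = [f"v{j}" for j in range(n_var)]
    variants = pd.DataFrame(
        {
            "id": ids,
            "chromosome": 1,
            "position": np.arange(1, n_var + 1) * 1000,
            "effect_allele": effect,
            "other_allele": other,
        }
    )
    d = pd.DataFrame(dosages.astype(float), columns=ids,
                     index=[f"s{i}" for i in range(n_sub)])
    return GenotypeData(d, variants)


@pytest.fixture
def cohort_with_planted_prs(rng):
    """Covariate/outcome table with a known PRS effect for model tests."""
    n = 2000
    prs = rng.standard_normal(n)
    age = rng.uniform(30, 95, n)
    age_c = age - age.mean()
    sex = (rng.random(n) < 0.5).astype(float)
    table = pd.DataFrame(
        {
            "prs_z": prs,
            "age": age,
            "sex": sex,
            **{f"PC{j}": rng.standard_normal(n) for j in range(1, 7)},
        }
    )
    table["score"] = (
        5.0 - 0.5 * prs - 0.02 * age_c - 0.001 * age_c**2 + 0.2 * sex
        + rng.normal(0, 1.0, n)
    )
    return table
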