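"""Synthetic cohort generator: genotypes, GWAS weights, covariates, outcomes.

The generator emulates a population-based cohort of adults aged 30-95 with
array genotypes, a GWAS weight table whose genome-wide significant subset
drives a polygenic risk score (PRS), and a battery of cognitive and
oculomotor outcome scores generated from a known linear model

    outcome = b0 + b_prs*PRS_z + b_age*age_c + b_age2*age_c^2 + b_sex*sex
              + b_prs_age*PRS_z*age_c + b_prs_age2*PRS_z*age_c^2 + noise

with mean-centred age, plus one bounded outcome ("antisaccade correction
rate", scaled to (0, 1]) generated from a one-inflated beta mechanism:
with probability sigmoid(g0 + g1*PRS_z) the subject corrects every error
(outcome exactly 1), otherwise the outcome is Beta(mu*phi, (1-mu)*phi)
with logit(mu) = m0 + m1*PRS_z.

Every outcome's baseline level and residual scale default to magnitudes
typical of population cohort studies of this battery, so planted effects
are expressed in natural units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from gazeprs.genetics import GENOME_WIDE_THRESHOLD, GenotypeData, PRSVector
from gazeprs.stats.linear import LOG_TRANSFORM_OUTCOMES

__all__ = [
    "CohortConfig",
    "TrueEffects",
    "OUTCOME_NAMES",
    "default_effect_table",
    "simulate_genotypes",
    "simulate_weight_table",
    "simulate_covariates_outcomes",
]


@dataclass(frozen=True)
class CohortConfig:
    """Size and genetic architecture of a simulated cohort."""

    n_subjects: int = 5182
    age_range: tuple[float, float] = (30.0, 95.0)
    sex_ratio: float = 0.558  # proportion female
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_snps: int = 0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi < 0.5 + 1e-12:
            raise ValueError(f"MAF range must satisfy 0 < low <= high < 0.5, got {self.maf_range}")
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps cannot exceed n_snps")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be a proportion")


@dataclass(frozen=True)
class TrueEffects:
    """Generating coefficients for one outcome (natural units)."""

    beta0: float = 0.0
    beta_prs: float = 0.0
    beta_age: float = 0.0
    beta_age2: float = 0.0
    beta_sex: float = 0.0
    beta_prs_by_age: float = 0.0
    beta_prs_by_age2: float = 0.0
    sigma: float = 1.0
    # (logistic intercept, logistic PRS slope, beta-mean intercept,
    #  beta-mean PRS slope, precision phi) for the one-inflated outcome
    oneinfl_params: tuple[float, float, float, float, float] = (
        1.25,
        0.0,
        0.85,
        0.0,
        10.0,
    )

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.oneinfl_params[4] <= 0:
            raise ValueError("precision phi must be positive")


#: The 27 linear-model outcomes plus the one-inflated correction rate,
#: mirroring a 28-comparison family (working/episodic memory, processing
#: speed, executive function, vocabulary, fixation, pursuit, pro/antisaccade).
OUTCOME_NAMES = (
    "digit_span_forward",
    "digit_span_backward",
    "corsi_forward",
    "corsi_backward",
    "avlt_immediate",
    "avlt_delayed",
    "word_fluency",
    "tmt_a",
    "tmt_b",
    "mwt_b",
    "fixation_spatial_error",
    "fixation_saccade_rate",
    "fixation_blink_rate",
    "spem_velocity_gain",
    "spem_saccade_rate",
    "prosaccade_latency",
    "prosaccade_amplitude_gain",
    "prosaccade_spatial_error",
    "prosaccade_peak_velocity",
    "prosaccade_adjusted_peak_velocity",
    "antisaccade_latency",
    "antisaccade_amplitude_gain",
    "antisaccade_spatial_error",
    "antisaccade_peak_velocity",
    "antisaccade_adjusted_peak_velocity",
    "antisaccade_costs",
    "antisaccade_error_rate",
    "antisaccade_correction_rate",
)

# baseline mean / residual SD per outcome (cohort-typical magnitudes);
# positive-only outcomes are generated on the log scale downstream of these
_BASELINES: dict[str, tuple[float, float]] = {
    "digit_span_forward": (6.4, 1.2),
    "digit_span_backward": (4.8, 1.2),
    "corsi_forward": (4.9, 1.1),
    "corsi_backward": (4.8, 1.0),
    "avlt_immediate": (51.3, 10.1),
    "avlt_delayed": (10.3, 3.3),
    "word_fluency": (26.4, 6.9),
    "tmt_a": (3.5, 0.35),  # log-seconds
    "tmt_b": (3.8, 0.45),  # log-seconds
    "mwt_b": (30.6, 3.4),
    "fixation_spatial_error": (-0.1, 0.3),  # log-deg
    "fixation_saccade_rate": (-1.6, 0.5),  # log-(N/s)
    "fixation_blink_rate": (-2.3, 0.9),  # log-(N/s)
    "spem_velocity_gain": (78.1, 16.3),
    "spem_saccade_rate": (2.2, 0.6),
    "prosaccade_latency": (190.6, 28.4),
    "prosaccade_amplitude_gain": (93.8, 6.7),
    "prosaccade_spatial_error": (2.1, 0.5),  # log-%
    "prosaccade_peak_velocity": (364.8, 57.6),
    "prosaccade_adjusted_peak_velocity": (3.9, 0.6),
    "antisaccade_latency": (282.0, 50.6),
    "antisaccade_amplitude_gain": (112.0, 27.8),
    "antisaccade_spatial_error": (3.3, 0.6),  # log-%
    "antisaccade_peak_velocity": (346.6, 67.3),
    "antisaccade_adjusted_peak_velocity": (3.2, 0.8),
    "antisaccade_costs": (91.8, 43.1),
    "antisaccade_error_rate": (31.6, 23.6),
}


def default_effect_table() -> dict[str, TrueEffects]:
    """Null-effect generating model for the full 28-outcome family.

    Each outcome gets its cohort-typical baseline and residual SD, a mild
    age trend (about a quarter of a residual SD per decade, with a small
    quadratic term) and no PRS effect; plant effects by replacing entries.
    """
    table: dict[str, TrueEffects] = {}
    for name in OUTCOME_NAMES:
        if name == "antisaccade_correction_rate":
            table[name] = TrueEffects(oneinfl_params=(1.25, 0.0, 0.85, 0.0, 10.0))
            continue
        mean, sd = _BASELINES[name]
        table[name] = TrueEffects(
            beta0=mean,
            beta_age=-0.025 * sd,
            beta_age2=-0.0004 * sd,
            beta_sex=0.1 * sd,
            sigma=sd,
        )
    return table


def simulate_genotypes(config: CohortConfig) -> GenotypeData:
    """Binomial(2, MAF) dosages per variant, with optional missingness.

    Variant MAFs are drawn uniformly from ``config.maf_range``; alleles are
    random non-ambiguous pairs.  With ``missing_rate`` > 0, entries are set
    missing completely at random.
    """
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    dosages = rng.binomial(2, mafs, size=(config.n_subjects, config.n_snps)).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
    alleles = [pairs[i] for i in rng.integers(0, len(pairs), config.n_snps)]
    variants = pd.DataFrame(
        {
            "id": [f"rs{100000 + i}" for i in range(config.n_snps)],
            "chromosome": rng.integers(1, 23, config.n_snps),
            "position": np.sort(rng.integers(1, 5_000_000, config.n_snps)),
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "true_maf": mafs,
        }
    )
    subjects = [f"S{i:05d}" for i in range(config.n_subjects)]
    return GenotypeData(
        pd.DataFrame(dosages, index=subjects, columns=variants["id"]),
        variants,
    )


def simulate_weight_table(
    variants: pd.DataFrame,
    n_significant: int,
    seed: int = 0,
    effect_sd: float = 0.15,
) -> pd.DataFrame:
    """GWAS-style weight table: exactly ``n_significant`` variants pass 5e-8.

    Effect weights are log-odds-scale draws N(0, effect_sd); the first
    ``n_significant`` variants (in table order) receive p-values strictly
    below the genome-wide threshold, the rest strictly above, so the
    significance filter is exercised deterministically.
    """
    n = len(variants)
    if n_significant > n:
        raise ValueError("n_significant cannot exceed the number of variants")
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.0, effect_sd, size=n)
    pvals = np.empty(n)
    pvals[:n_significant] = 10 ** rng.uniform(-30, np.log10(GENOME_WIDE_THRESHOLD) - 0.01, n_significant)
    pvals[n_significant:] = rng.uniform(GENOME_WIDE_THRESHOLD, 1.0, n - n_significant)
    return pd.DataFrame(
        {
            "variant_id": variants["id"].to_numpy(),
            "effect_allele": variants["effect_allele"].to_numpy(),
            "weight": weights,
            "pvalue": pvals,
        }
    )


def simulate_covariates_outcomes(
    config: CohortConfig,
    effects: dict[str, TrueEffects] | TrueEffects,
    prs_z: PRSVector | pd.Series,
    seed: int | None = None,
) -> pd.DataFrame:
    """Covariate + outcome table from the planted generating model.

    Age is uniform over the configured range, sex Bernoulli (1 = female),
    six PC-like covariates standard normal.  ``effects`` maps outcome name
    to its generating coefficients (a single TrueEffects generates one
    outcome named "outcome").  The outcome named
    "antisaccade_correction_rate" is drawn from the one-inflated beta
    mechanism; all others are Gaussian around the linear predictor.
    """
    z = prs_z.z if isinstance(prs_z, PRSVector) else pd.Series(prs_z)
    if len(z) != config.n_subjects:
        raise ValueError(
            f"PRS length {len(z)} does not match n_subjects {config.n_subjects}"
        )
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = config.n_subjects
    age = rng.uniform(*config.age_range, size=n)
    sex = (rng.random(n) < config.sex_ratio).astype(float)
    pcs = rng.standard_normal((n, 6))
    table = pd.DataFrame(
        {
            "subject_id": np.asarray(z.index)
            if isinstance(z.index, pd.Index) and z.index.dtype == object
            else [f"S{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            **{f"PC{j + 1}": pcs[:, j] for j in range(6)},
            "prs_z": np.asarray(z, dtype=float),
        }
    )
    age_c = age - age.mean()
    zv = np.asarray(z, dtype=float)
    if isinstance(effects, TrueEffects):
        effects = {"outcome": effects}
    for name, eff in effects.items():
        if name == "antisaccade_correction_rate":
            g0, g1, m0, m1, phi = eff.oneinfl_params
            p1 = expit(g0 + g1 * zv)
            is_one = rng.random(n) < p1
            mu = expit(m0 + m1 * zv)
            y = rng.beta(mu * phi, (1.0 - mu) * phi)
            y = np.clip(y, 1e-9, 1.0 - 1e-9)
            y[is_one] = 1.0
            table[name] = y
        else:
            lin = (
                eff.beta0
                + eff.beta_prs * zv
                + eff.beta_age * age_c
                + eff.beta_age2 * age_c**2
                + eff.beta_sex * sex
                + eff.beta_prs_by_age * zv * age_c
                + eff.beta_prs_by_age2 * zv * age_c**2
            )
            raw = lin + rng.normal(0.0, eff.sigma, size=n)
            # skewed outcomes are generated on the log scale (their
            # baselines are log-units) and exponentiated, so the analysis
            # model's log transform recovers the planted coefficients
            if name in LOG_TRANSFORM_OUTCOMES:
                raw = np.exp(raw)
            table[name] = raw
    return table
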