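# Methods

This note documents the models, algorithms and design choices implemented
in `gazeprs`, including where the underlying literature is silent and a
convention had to be fixed.

## Oculomotor signal processing

**Kinematics.** Gaze position (degrees of visual angle, centre origin) is
pre-smoothed with a 7-sample moving average, differentiated with a 5-point
central difference, and the resulting velocity traces are smoothed with a
9-sample moving average. At 1000 Hz this chain keeps the speed noise from
0.1° per-sample position noise well below the 22°/s detection threshold
(≈4°/s SD) while shifting noise-free saccade onsets by under 1 ms.
Acceleration is the first difference of smoothed speed. Kinematics are
masked within 50 ms of flagged blink samples; blink intervals closer than
their padding are merged.

**Saccade detection.** Samples satisfying speed ≥ 60°/s, or speed ≥ 22°/s
together with |acceleration| ≥ 3800°/s², seed candidate events. Runs are
extended outward while the speed stays above a 10°/s floor (capped at
40 ms per side so noise cannot walk the boundary away), merged when
separated by less than 20 ms (suppresses double-counting of dynamic
overshoot), and discarded when the onset-to-offset displacement is ≤ 1°.
Event boundaries at low-velocity crossings are the least-surprising
convention where only the detection criteria are prescribed. A practical
consequence of the velocity smoothing is that the acceleration route only
fires for velocity transients sharper than the smoothing scale (roughly a
50°/s step); for main-sequence-compliant saccades any event above the 1°
amplitude floor already exceeds 60°/s peak velocity, so the velocity
criterion dominates.

**Trial rules.** A saccade-task trial is valid when the 100 ms before
target onset are free of saccades and blinks, mean gaze in that window is
within 3° of the fixation point, the first saccade after target onset has
latency ≥ 80 ms (else `anticipatory`), and it ends before the target
times out. The initial saccade is the first detected saccade after target
onset. Trials are mirrored to a canonical rightward frame so one code
path scores both sides. Spatial error is |landing − required|/9.63 × 100,
commensurate with amplitude gain; the required position is the target
(prosaccade) or its mirror (antisaccade). A direction error is corrected
iff a later saccade moves toward the mirror position and its endpoint
reaches or crosses the midline before target offset.

**Aggregation.** Outcome means require ≥ 7 valid-and-correct trials;
the direction error rate requires only valid trials; the correction rate
requires ≥ 5 direction errors and ≥ 1 correction. Below-threshold
outcomes are absent (NaN in memory, empty TSV fields), never zero —
conflating the two would bias cohort-level models.

**Fixation.** Fixation periods are ≥ 100 ms stretches free of saccades
and blinks, split at target steps, whose mean gaze lies within 3° of the
current target ("directed toward the target"); the spatial error is the
RMS Euclidean distance to the target over those periods (with isotropic
per-axis noise σ this converges to σ√2). Saccade and blink rates divide
event counts by the full task duration.

**Pursuit.** Samples with speed < 30°/s sustained ≥ 50 ms count as
pursuit. A half-cycle of target motion runs between successive position
extremes (the first extreme a quarter period after motion onset), so its
middle two temporal quarters straddle the velocity peak; the gain is the
ratio of mean horizontal eye velocity to mean target velocity over
pursuit samples in those quarters, averaged over half-cycles, in percent.
Anchoring half-cycles at zero crossings instead would place a velocity
zero in the denominator and make the ratio numerically unstable.

## Genetics

QC drops variants with call rate < 0.99, folded MAF < 0.01 or exact
Hardy-Weinberg p < 10⁻⁶, and samples with call rate < 0.95 or
heterozygosity beyond ±3 SD of the cohort mean (the literature's
"abnormal heterozygosity" quantified). Because removing samples shifts
variant statistics and vice versa, the two rule sets are re-applied to a
fixpoint, which makes the filter idempotent. Relatedness and sex-mismatch
checks need IBD/sex-chromosome data the synthetic module does not model;
their reason codes are reserved in the report schema.

The HWE test is the standard exact conditional test: given the allele
counts, the probability of each attainable heterozygote count is summed
over configurations no more probable than the observed one (ties included
in the tail). Log-gamma arithmetic with renormalization keeps absolute
error below 10⁻¹³ for cohort-scale tables; the test suite checks every
table with total ≤ 200 against an exact-rational enumeration.

PRS dosages are counted on the weight table's effect allele, flipping to
2 − dosage when the genotype file counts the other allele;
strand-ambiguous (A/T, C/G) variants are kept with a warning since silent
dropping would surprise users of synthetic data with controlled alleles.
Missing dosages are imputed with the per-variant cohort mean (the
PLINK-score default behaviour). z-standardization uses the population SD
(ddof = 0), so scores have mean 0 and SD exactly 1 over the cohort.
Principal components are the orthonormal left singular vectors of the
column-standardized dosage matrix with sign fixed by the
largest-magnitude loading.

## Association statistics

The association model is OLS of each outcome on the z-standardized PRS
with mean-centred age, its square, sex and six PCs; centring age before
squaring reduces collinearity between the linear and quadratic terms.
Seven right-skewed outcomes (trail-making A/B completion times, the
pro/antisaccade spatial errors and the three fixation measures) are
natural-log transformed; the hard-coded list lives in
`stats.linear.LOG_TRANSFORM_OUTCOMES`.

The gene–age interaction test adds PRS×age_c and PRS×age_c² and reports
the nested-model F statistic with 2 numerator df as the primary result —
for Gaussian linear models the F statistic and the likelihood-ratio χ²
are monotone transforms, and the F form is the one conventionally
tabulated — with the asymptotic LRT alongside.

FDR control is Benjamini–Hochberg with a *fixed* family denominator m
(default 28 per PRS score: 27 linear outcomes plus the correction rate),
applied separately per score, with the running-minimum enforcement and a
cap at 1. Risk groups split the PRS at z = ±1, boundary values assigned
to the medium group ("between −1 and 1" read as inclusive). Tukey
contrasts compare group-specific *marginal linear age trends* — the
derivative of the fitted age curve averaged over observed ages, which
with centred age is the group's linear age coefficient — using the
studentized-range distribution with k = 3; comparing slopes at a single
reference age would be the main alternative, and the averaged-trend
convention is the one implemented.

Missing covariates are completed by predictive mean matching: each
incomplete covariate is regressed on the complete ones, each missing case
matched to the k = 5 donors with nearest predicted values, the model
refitted on 10 bootstrap resamples, and the imputation drawn from the
pooled donors, so imputed values always lie in the observed support.

**One-inflated beta regression.** Outcomes in (0, 1] with positive mass
at exactly 1 are modelled as a mixture: P(y=1|x) = σ(x'γ) and, for y < 1,
y ~ Beta(μφ, (1−μ)φ) with logit(μ) = x'β and precision φ > 0. The joint
log-likelihood factorizes into the logistic and beta parts, so the joint
maximum coincides with part-wise maxima; the implementation nevertheless
optimizes the full parameter vector (γ, β, log φ) jointly with BFGS from
moment-based starting values and an analytic score, and the test suite
verifies the factorization against an independent logistic fit. Standard
errors come from the numerical observed information; effects on the
one-inflation probability are reported as odds ratios with Wald 95%
intervals. The beta part models y directly; effects on the complementary
fraction (e.g. errors left uncorrected) are the sign-flipped transform of
the same coefficients and are exposed as such. Fitting requires at least
one outcome at 1 and one below 1; anything else is a degeneracy error,
and non-convergence is flagged rather than silently accepted.

## Power

Power of the F-test for one added predictor is P(F′ > F_crit) with F′
noncentral F(df1, n − df1 − 1, λ), λ = f²·n (the fixed-model R²-increase
convention; the alternative λ = f²·df_res differs negligibly at cohort
sizes but the convention is pinned). The inverse solves power(f²) =
target by bracketed root search to 10⁻⁸. At n = 5182 and α = 0.05 this
yields 89.6%, 79.6% and 62.4% power at f² = 0.0020, 0.0015 and 0.0010,
and detectable effects of 0.0015 (80% power) and 0.0020 (90%).

## Synthetic-data generator

The generator emulates a population cohort aged 30–95 (age drawn uniform:
a uniform design maximizes interaction-detection power in tests, unlike
the middle-heavy age pyramid of a real cohort), sex ≈ 56% female,
genotypes Binomial(2, MAF) without linkage disequilibrium, and a
28-outcome battery whose baselines and residual scales are set to
magnitudes typical of published cohort descriptives (e.g. Corsi forward
4.9 ± 1.1 blocks, prosaccade latency 190.6 ± 28.4 ms). Outcomes follow
the same linear model the analysis fits, with configurable PRS, age,
age², sex and PRS×age coefficients; skewed outcomes are generated on the
log scale and exponentiated so the analysis transform recovers the
planted coefficients. The correction-rate outcome follows the
one-inflated beta mechanism with defaults anchored to realistic cohort
behaviour (about 78% of subjects correcting every error: logistic
intercept 1.25; β-part mean 0.7, φ = 10).

Gaze sessions use the task geometry of a standard battery (targets at
±9.63°, 0.5 Hz pursuit over ten cycles, 30 saccade trials with 1–2 s
uniform centre holds — the inter-trial jitter distribution is assumed
uniform — plus six antisaccade practice trials). Saccades have
raised-cosine velocity profiles with main-sequence peaks
V_peak = V_max(1 − e^(−A/c)); V_max = 500°/s with c = 7.5° puts a 9.63°
saccade at ≈361°/s peak velocity, matching adult population magnitudes.
Latencies are truncated normal with an 80 ms floor so no synthetic
saccade violates the analysis exclusion rule by construction; antisaccade
direction errors occur with a configurable probability, each followed by
a midline-crossing correction with the correction probability. Blinks
freeze the trace, set the flag, and are scheduled away from planned
saccades so the ground-truth event log stays exact. The generator does
not model pupil size, vertical saccade tasks, LD between variants,
oculomotor drift/calibration error, or realistic EyeLink event records
(a minimal ASC-like text importer is provided instead) — so passing tests
demonstrate algorithmic correctness on idealized physiology, not
robustness to every artifact of real recordings.

## Pipeline

One `RunConfig` (YAML round-trippable) drives simulate → QC → PRS (three
weight tables, mirroring a three-score design with a 28-comparison FDR
family per score) → outcomes → associations/interactions → risk groups →
power, with every stage seeded from one root seed; rerunning a config is
byte-identical. Classical cognitive scores are administered instruments,
not signal-derived quantities, so the analysis cohort's outcomes come
from the statistical generator; the gaze-simulation → event-detection →
scoring path runs for a configurable demonstration subset
(`n_gaze_subjects`, default 20) on every run, which keeps a full
5000-subject run in seconds while still exercising the signal chain
end-to-end. Problem sizes in the test suite follow the same logic:
detector fidelity is established on 100 single-subject sessions and
statistical calibration on hundreds of replicates at n = 3000–10000,
sizes at which every binomial acceptance band is decisive.

## Known limitations

* The beta-part precision φ is constant (no dispersion model), matching
  the two-part mean model; gamlss-style dispersion regression is out of
  scope.
* The exact HWE test is conservative at small sample sizes (discrete
  support); its null rejection rate approaches α only for cohort-scale n.
* PMM assumes missingness only in covariates and linear predictive
  models; outcome or PRS missingness is rejected by design.
* The detector's acceleration route is largely redundant at 1000 Hz with
  the chosen smoothing (see above); at lower sampling rates the smoothing
  windows (defined in samples) would need retuning.
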