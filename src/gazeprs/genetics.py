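"""Variant/sample QC, polygenic risk scores and population structure.

A genotype dataset is a pair of aligned tables: a subjects-by-variants dosage
matrix (entries in [0, 2], NaN for missing calls) and a variant table with
one row per variant (id, chromosome, position, effect/other allele).  The
polygenic risk score (PRS) of a subject is the weighted sum of effect-allele
dosages over the variants of a genome-wide association study (GWAS) weight
table, restricted to genome-wide significant variants (p < 5e-8), and is
z-standardized over the cohort before use as a predictor.

Quality control follows standard array-genotyping practice: variants are
dropped for low call rate, low minor allele frequency or departure from
Hardy-Weinberg equilibrium (exact test); samples are dropped for low call
rate or outlying heterozygosity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeData",
    "PRSVector",
    "QCThresholds",
    "GENOME_WIDE_THRESHOLD",
    "hwe_exact_test",
    "qc_filter",
    "select_genome_wide_significant",
    "compute_prs",
    "compute_pcs",
    "prs_correlations",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_weight_table",
    "read_vcf_dosages",
    "write_vcf_dosages",
]

#: GWAS genome-wide significance threshold; the filter keeps p strictly below.
GENOME_WIDE_THRESHOLD = 5e-8

VARIANT_COLUMNS = ["id", "chromosome", "position", "effect_allele", "other_allele"]

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class GenotypeData:
    """Dosage matrix (subjects x variants) plus its variant table.

    ``dosages`` is indexed by subject id with one column per variant id;
    ``variants`` has columns ``id, chromosome, position, effect_allele,
    other_allele`` (dosages count the effect allele).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants["id"]):
            raise ValueError("dosage columns must match variant table ids in order")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PRSVector:
    """Per-subject polygenic score: raw weighted sum and cohort z-score."""

    raw: pd.Series
    z: pd.Series
    n_snps_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.raw.index, "raw": self.raw.values, "z": self.z.values}
        )


@dataclass(frozen=True)
class QCThresholds:
    variant_call_rate: float = 0.99
    maf: float = 0.01
    hwe_p: float = 1e-6
    sample_call_rate: float = 0.95
    heterozygosity_sd: float = 3.0


def _hwe_log_probs(n_total: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every attainable heterozygote count.

    Conditional on ``n_total`` diploid genotypes carrying ``n_rare`` copies of
    the rarer allele, the heterozygote count h ranges over values with the
    parity of ``n_rare`` such that both homozygote counts are non-negative.
    """
    n_common = 2 * n_total - n_rare
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hs) // 2
    hom_common = n_total - hs - hom_rare
    keep = hom_common >= 0
    hs, hom_rare, hom_common = hs[keep], hom_rare[keep], hom_common[keep]
    logp = (
        gammaln(n_total + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hs + 1)
        - gammaln(hom_common + 1)
        + hs * math.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(2 * n_total + 1)
    )
    return hs, logp


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one (ties on
    probability fall in the tail).  A monomorphic variant has a single
    attainable configuration and returns p = 1.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n_total = sum(counts)
    if n_total == 0:
        raise ValueError("all genotype counts are zero")
    n_ref = 2 * n_hom_ref + n_het
    n_rare = min(n_ref, 2 * n_total - n_ref)
    hs, logp = _hwe_log_probs(n_total, n_rare)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hs, n_het)]
    # relative tolerance so float noise cannot drop a genuine tie
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def folded_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency (folded to [0, 0.5]) from dosages with NaN."""
    freq = np.nanmean(dosages) / 2.0
    return float(min(freq, 1.0 - freq))


def _hard_calls(col: np.ndarray) -> tuple[int, int, int]:
    called = col[~np.isnan(col)]
    g = np.rint(called).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def qc_filter(
    genotypes: GenotypeData, thresholds: QCThresholds | None = None
) -> tuple[GenotypeData, pd.DataFrame]:
    """Drop failing variants and samples; return filtered data plus report.

    Variant rules: call rate < ``variant_call_rate``, folded MAF <
    ``maf``, or HWE exact p < ``hwe_p``.  Sample rules (applied on the
    variant-filtered matrix): call rate < ``sample_call_rate`` or
    heterozygosity beyond ``heterozygosity_sd`` SDs of the cohort mean.
    Because removing samples shifts variant statistics (and vice versa),
    the two rule sets are re-applied until a full pass excludes nothing,
    which makes the filter idempotent.  The report has one row per
    exclusion: unit, id, reason, value.  Reason codes
    ``cryptic_relatedness`` and ``sex_mismatch`` are reserved in the
    schema but never emitted (they need data this pipeline does not model).
    """
    thr = thresholds or QCThresholds()
    all_rows: list[dict] = []
    current = genotypes
    for _ in range(100):
        current, rows = _qc_pass(current, thr)
        all_rows.extend(rows)
        if not rows:
            break
    report = pd.DataFrame(all_rows, columns=["unit", "id", "reason", "value"])
    return current, report


def _qc_pass(
    genotypes: GenotypeData, thr: QCThresholds
) -> tuple[GenotypeData, list[dict]]:
    rows: list[dict] = []
    d = genotypes.dosages
    n_sub = d.shape[0]

    call_rate = 1.0 - d.isna().sum(axis=0).to_numpy() / n_sub
    keep_variant = np.ones(d.shape[1], dtype=bool)
    for j, vid in enumerate(d.columns):
        col = d.iloc[:, j].to_numpy(dtype=float)
        if call_rate[j] < thr.variant_call_rate:
            keep_variant[j] = False
            rows.append(
                dict(unit="variant", id=vid, reason="call_rate", value=call_rate[j])
            )
            continue
        maf = folded_maf(col)
        if maf < thr.maf:
            keep_variant[j] = False
            rows.append(dict(unit="variant", id=vid, reason="maf", value=maf))
            continue
        p = hwe_exact_test(*_hard_calls(col))
        if p < thr.hwe_p:
            keep_variant[j] = False
            rows.append(dict(unit="variant", id=vid, reason="hwe", value=p))

    d2 = d.loc[:, keep_variant]
    if d2.shape[1] == 0:
        raise ValueError("no variants remain after QC filtering")

    arr = d2.to_numpy(dtype=float)
    sample_call = 1.0 - np.isnan(arr).sum(axis=1) / arr.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        het = np.nanmean(np.rint(arr) == 1, axis=1)
    keep_sample = np.ones(n_sub, dtype=bool)
    for i, sid in enumerate(d2.index):
        if sample_call[i] < thr.sample_call_rate:
            keep_sample[i] = False
            rows.append(
                dict(unit="sample", id=sid, reason="call_rate", value=sample_call[i])
            )
    het_ok = het[keep_sample]
    mu, sd = float(np.mean(het_ok)), float(np.std(het_ok))
    if sd > 0:
        for i, sid in enumerate(d2.index):
            if keep_sample[i] and abs(het[i] - mu) > thr.heterozygosity_sd * sd:
                keep_sample[i] = False
                rows.append(
                    dict(unit="sample", id=sid, reason="heterozygosity", value=het[i])
                )
    d3 = d2.loc[keep_sample]
    if d3.shape[0] == 0:
        raise ValueError("no samples remain after QC filtering")
    variants = genotypes.variants.loc[keep_variant].reset_index(drop=True)
    return GenotypeData(d3, variants), rows


def select_genome_wide_significant(
    weights: pd.DataFrame, threshold: float = GENOME_WIDE_THRESHOLD
) -> pd.DataFrame:
    """Keep weight-table rows with p-value strictly below ``threshold``."""
    return weights.loc[weights["pvalue"] < threshold].reset_index(drop=True)


def compute_prs(genotypes: GenotypeData, weights: pd.DataFrame) -> PRSVector:
    """Weighted sum of effect-allele dosages, z-standardized over the cohort.

    Dosages are counted on the weight table's effect allele: when the
    genotype file counts the other allele the dosage is flipped to
    ``2 - dosage``.  Missing dosages are imputed with the cohort mean
    dosage of that variant.  The z-score uses the population SD (ddof=0),
    so z has mean 0 and SD exactly 1 over the cohort.
    """
    if weights.empty:
        raise ValueError("weight table is empty; PRS undefined")
    if weights["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in weight table")
    vt = genotypes.variants.set_index("id")
    missing = [v for v in weights["variant_id"] if v not in vt.index]
    if missing:
        raise KeyError(f"variants absent from genotypes: {missing}")

    score = np.zeros(genotypes.n_subjects)
    for _, row in weights.iterrows():
        vid = row["variant_id"]
        eff = str(row["effect_allele"]).upper()
        geno_eff = str(vt.loc[vid, "effect_allele"]).upper()
        geno_oth = str(vt.loc[vid, "other_allele"]).upper()
        if frozenset((geno_eff, geno_oth)) in _AMBIGUOUS_PAIRS:
            warnings.warn(
                f"strand-ambiguous variant {vid} ({geno_eff}/{geno_oth}) kept",
                stacklevel=2,
            )
        dos = genotypes.dosages[vid].to_numpy(dtype=float)
        if eff == geno_eff:
            pass
        elif eff == geno_oth:
            dos = 2.0 - dos
        else:
            raise ValueError(
                f"allele mismatch for {vid}: weight effect allele {eff} "
                f"not in genotype alleles {geno_eff}/{geno_oth}"
            )
        if np.isnan(dos).any():
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        score += float(row["weight"]) * dos

    raw = pd.Series(score, index=genotypes.dosages.index, name="raw")
    sd = float(np.std(score))
    if sd == 0:
        raise ValueError("PRS has zero variance; cannot z-standardize")
    z = (raw - raw.mean()) / sd
    z.name = "z"
    return PRSVector(raw=raw, z=z, n_snps_used=len(weights))


def compute_pcs(genotypes: GenotypeData, k: int = 6) -> pd.DataFrame:
    """Principal-component coordinates of the standardized dosage matrix.

    Columns are mean-centred and scaled to unit variance (zero-variance
    variants dropped with a warning); the returned subject coordinates are
    the orthonormal left singular vectors, with each component's sign fixed
    so its largest-magnitude variant loading is positive.  Rank deficiency
    yields fewer components with a warning.
    """
    arr = genotypes.dosages.to_numpy(dtype=float)
    if np.isnan(arr).any():
        col_mean = np.nanmean(arr, axis=0)
        arr = np.where(np.isnan(arr), col_mean, arr)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} zero-variance variants from PCA")
    x = (arr[:, ok] - mu[ok]) / sd[ok]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    n_comp = min(k, rank)
    if n_comp < k:
        warnings.warn(f"rank-deficient matrix: returning {n_comp} of {k} PCs")
    u, vt = u[:, :n_comp], vt[:n_comp]
    for j in range(n_comp):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    return pd.DataFrame(
        u,
        index=genotypes.dosages.index,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )


def prs_correlations(**scores: PRSVector | pd.Series) -> pd.DataFrame:
    """Pearson correlation matrix between named PRS vectors."""
    cols = {}
    for name, s in scores.items():
        v = s.z if isinstance(s, PRSVector) else pd.Series(s)
        if float(np.std(v)) == 0:
            raise ValueError(f"score {name!r} has zero variance")
        cols[name] = np.asarray(v, dtype=float)
    lengths = {len(v) for v in cols.values()}
    if len(lengths) > 1:
        raise ValueError("PRS vectors have differing lengths")
    return pd.DataFrame(cols).corr(method="pearson")


# ---------------------------------------------------------------------------
# File interfaces


def write_dosage_tsv(genotypes: GenotypeData, dosage_path, variant_path) -> None:
    genotypes.dosages.to_csv(dosage_path, sep="\t", index_label="subject_id", na_rep="NA")
    genotypes.variants.to_csv(variant_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, variant_path) -> GenotypeData:
    d = pd.read_csv(dosage_path, sep="\t", index_col="subject_id", na_values="NA")
    v = pd.read_csv(variant_path, sep="\t")
    return GenotypeData(d, v)


def read_weight_table(path) -> pd.DataFrame:
    """Read a PLINK-score-style weight TSV: variant_id, effect_allele, weight[, pvalue]."""
    w = pd.read_csv(path, sep="\t")
    required = {"variant_id", "effect_allele", "weight"}
    if not required.issubset(w.columns):
        raise ValueError(f"weight table must have columns {sorted(required)}")
    if "pvalue" not in w.columns:
        w["pvalue"] = np.nan
    return w


def write_vcf_dosages(genotypes: GenotypeData, path) -> None:
    """Write genotypes as a minimal VCF with a FORMAT/DS dosage field."""
    subjects = list(genotypes.dosages.index.astype(str))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(subjects) + "\n")
        for j, row in genotypes.variants.iterrows():
            dos = genotypes.dosages.iloc[:, j]
            vals = ["." if pd.isna(x) else f"{x:g}" for x in dos]
            fh.write(
                f"{row['chromosome']}\t{row['position']}\t{row['id']}\t"
                f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t.\tDS\t"
                + "\t".join(vals)
                + "\n"
            )


def read_vcf_dosages(path) -> GenotypeData:
    """Read dosages from the DS field of a VCF (ALT counted as effect allele)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    cols, records = {}, []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        cols[vid] = ds
        records.append(
            dict(
                id=vid,
                chromosome=var.CHROM,
                position=var.POS,
                effect_allele=var.ALT[0],
                other_allele=var.REF,
            )
        )
    dosages = pd.DataFrame(cols, index=subjects)
    return GenotypeData(dosages, pd.DataFrame(records, columns=VARIANT_COLUMNS))
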