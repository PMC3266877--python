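"""Sample- and SNP-level quality control for case-control genotype panels.

Implements the usual battery applied before a genome-wide scan: per-sample
and per-group per-SNP call rates, minor-allele-frequency floors evaluated in
cases and controls separately, the Hardy-Weinberg exact test in controls,
method-of-moments identity-by-descent relatedness with greedy removal of one
member per related pair, PCA-based ancestry outlier detection, and the
genomic-control inflation factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .containers import (
    MISSING,
    GenotypeCounts,
    GenotypeMatrix,
    SlepipeError,
)

__all__ = [
    "QcThresholds",
    "QcReport",
    "IbdEstimate",
    "hwe_exact_test",
    "filter_samples_by_call_rate",
    "filter_snps",
    "estimate_ibd",
    "flag_related_pairs",
    "ld_prune",
    "pca_ancestry_outliers",
    "lambda_gc",
    "run_qc",
]

#: Median of the 1-df chi-square distribution, the genomic-control null median.
CHI2_1DF_MEDIAN = float(chi2.ppf(0.5, 1))


@dataclass(frozen=True)
class QcThresholds:
    """QC cutoffs.

    Defaults follow standard array-GWAS practice: samples below 98% call
    rate are dropped; SNPs must reach 99% call rate and 1% MAF within each
    of the case and control panels, and controls must not violate
    Hardy-Weinberg at exact P < 1e-6.  All comparisons are strict ``<``.
    """

    sample_call_rate_min: float = 0.98
    snp_call_rate_min: float = 0.99
    maf_min: float = 0.01
    hwe_p_min: float = 1.0e-6
    pihat_relatedness_min: float = 0.1875
    pca_outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "snp_call_rate_min", "maf_min",
                     "hwe_p_min", "pihat_relatedness_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.pca_outlier_sd <= 0:
            raise ValueError("pca_outlier_sd must be > 0")


@dataclass
class IbdEstimate:
    """Method-of-moments IBD sharing for one sample pair."""

    sample_pair: tuple[str, str]
    z0: float
    z1: float
    z2: float
    pi_hat: float
    n_informative: int
    low_information: bool = False


@dataclass
class QcReport:
    """Exclusions with primary reason codes plus summary diagnostics."""

    excluded_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "reason", "value", "threshold"]))
    excluded_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["snp_id", "reason", "value", "threshold"]))
    lambda_gc: float | None = None
    pca_coordinates: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Two-sided exact Hardy-Weinberg test probability.

    Under the null, conditional on the observed allele counts, the number of
    heterozygotes follows the classical urn distribution; the returned
    P-value sums the probabilities of all heterozygote counts no more
    probable than the observed one (standard exact-test convention).
    Monomorphic tables return 1.0.
    """
    n = counts.n_called
    if n == 0:
        raise SlepipeError("HWE test on all-missing genotype counts")
    n_rare = min(counts.allele1_count, 2 * n - counts.allele1_count)
    if n_rare == 0:
        return 1.0
    obs_het = counts.n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | n, n_rare) up to the common normalising constant
    logp = (hets * math.log(2.0)
            - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1))
    logp -= logsumexp(logp)
    p_obs = logp[np.searchsorted(hets, obs_het)]
    # float-tolerant "no more probable than observed"
    keep = logp <= p_obs + 1e-12
    return float(min(1.0, math.exp(logsumexp(logp[keep]))))


def _hwe_p_vector(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    out = np.ones(len(n0))
    for i, (a, b, c) in enumerate(zip(n0, n1, n2)):
        if a + b + c == 0:
            out[i] = np.nan
            continue
        out[i] = hwe_exact_test(GenotypeCounts(int(a), int(b), int(c)))
    return out


# ---------------------------------------------------------------------------
# sample / SNP filters
# ---------------------------------------------------------------------------

def filter_samples_by_call_rate(
    genotypes: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> QcReport:
    """Flag samples whose genotype call rate falls below the threshold.

    The comparison is strict: a sample at exactly the threshold is retained.
    """
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise SlepipeError("empty genotype matrix")
    rates = genotypes.sample_call_rate()
    bad = rates < thresholds.sample_call_rate_min
    report = QcReport()
    report.excluded_samples = pd.DataFrame(
        {
            "sample_id": genotypes.samples.loc[bad, "sample_id"].to_numpy(),
            "reason": "sample_call_rate",
            "value": rates[bad],
            "threshold": thresholds.sample_call_rate_min,
        }
    )
    return report


def filter_snps(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
) -> QcReport:
    """Flag SNPs failing panel-level criteria, with one primary reason each.

    Rules are evaluated in a fixed order and the first failure becomes the
    primary reason code: per-group call rate, per-group MAF, control HWE,
    non-autosomal chromosome, and not-shared (no calls in one panel).  The
    "minor" allele is taken within each group separately.
    """
    status = genotypes.samples["status"]
    if status.isna().any():
        raise SlepipeError("every sample must carry a case/control status")
    case_mask = genotypes.case_mask
    ctrl_mask = genotypes.control_mask
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise SlepipeError("both cases and controls are required for SNP QC")

    cr_case = genotypes.snp_call_rate(case_mask)
    cr_ctrl = genotypes.snp_call_rate(ctrl_mask)
    f_case = genotypes.allele1_freq(case_mask)
    f_ctrl = genotypes.allele1_freq(ctrl_mask)
    maf_case = np.fmin(f_case, 1 - f_case)
    maf_ctrl = np.fmin(f_ctrl, 1 - f_ctrl)
    ctrl_counts = genotypes.stacked_genotype_counts(ctrl_mask)
    hwe_p = _hwe_p_vector(ctrl_counts["n0"].to_numpy(),
                          ctrl_counts["n1"].to_numpy(),
                          ctrl_counts["n2"].to_numpy())
    chroms = pd.to_numeric(genotypes.snps["chrom"], errors="coerce")
    autosomal = chroms.between(1, 22).to_numpy()
    shared = (cr_case > 0) & (cr_ctrl > 0)

    rules = [
        ("call_rate",
         (cr_case < thresholds.snp_call_rate_min)
         | (cr_ctrl < thresholds.snp_call_rate_min),
         np.fmin(cr_case, cr_ctrl), thresholds.snp_call_rate_min),
        ("maf",
         np.isnan(maf_case) | np.isnan(maf_ctrl)
         | (maf_case < thresholds.maf_min) | (maf_ctrl < thresholds.maf_min),
         np.fmin(maf_case, maf_ctrl), thresholds.maf_min),
        ("hwe",
         np.isnan(hwe_p) | (hwe_p < thresholds.hwe_p_min),
         hwe_p, thresholds.hwe_p_min),
        ("non_autosomal", ~autosomal, np.full(genotypes.n_snps, np.nan), np.nan),
        ("not_shared", ~shared, np.fmin(cr_case, cr_ctrl), 0.0),
    ]
    reason = np.full(genotypes.n_snps, "", dtype=object)
    value = np.full(genotypes.n_snps, np.nan)
    thr = np.full(genotypes.n_snps, np.nan)
    for name, mask, val, t in rules:
        new = mask & (reason == "")
        reason[new] = name
        value[new] = np.asarray(val, dtype=float)[new]
        thr[new] = t
    bad = reason != ""
    report = QcReport()
    report.excluded_snps = pd.DataFrame(
        {
            "snp_id": genotypes.snps.loc[bad, "snp_id"].to_numpy(),
            "reason": reason[bad],
            "value": value[bad],
            "threshold": thr[bad],
        }
    )
    return report


# ---------------------------------------------------------------------------
# relatedness (IBD method of moments)
# ---------------------------------------------------------------------------

def estimate_ibd(
    genotypes: GenotypeMatrix,
    pair: tuple[int | str, int | str],
    allele_freqs: np.ndarray | None = None,
) -> IbdEstimate:
    """PLINK-style method-of-moments IBD sharing from IBS counts.

    Expected identity-by-state probabilities given 0/1/2 alleles shared
    identical-by-descent are accumulated per SNP from sample allele
    frequencies; the observed IBS tallies are then solved for (z0, z1, z2),
    truncated to [0, 1] and renormalised.  pi_hat = z1/2 + z2.
    """
    ids = genotypes.samples["sample_id"]
    idx = [genotypes.samples.index[ids == s][0] if isinstance(s, str) else int(s)
           for s in pair]
    g1 = genotypes.genotypes[idx[0]].astype(float)
    g2 = genotypes.genotypes[idx[1]].astype(float)
    p = (allele_freqs if allele_freqs is not None
         else genotypes.allele1_freq())
    ok = (g1 != MISSING) & (g2 != MISSING) & np.isfinite(p) & (p > 0) & (p < 1)
    g1, g2, p = g1[ok], g2[ok], p[ok]
    n = len(p)
    if n == 0:
        raise SlepipeError("no informative SNPs for IBD estimation")
    q = 1 - p
    diff = np.abs(g1 - g2)
    n_ibs0 = float(np.sum(diff == 2))
    n_ibs1 = float(np.sum(diff == 1))
    n_ibs2 = float(np.sum(diff == 0))
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e2_ibd1 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))
    z0 = n_ibs0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    z1 = (n_ibs1 - z0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    z2 = (n_ibs2 - z0 * e2_ibd0 - z1 * e2_ibd1) / n
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pair_ids = (str(ids.iloc[idx[0]]), str(ids.iloc[idx[1]]))
    return IbdEstimate(
        sample_pair=pair_ids, z0=float(z[0]), z1=float(z[1]), z2=float(z[2]),
        pi_hat=float(z[1] / 2 + z[2]), n_informative=n,
        low_information=n < 100,
    )


def flag_related_pairs(
    estimates: list[IbdEstimate],
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
) -> pd.DataFrame:
    """Greedy exclusion of one member per related pair.

    Pairs with pi_hat at or above the threshold are processed in descending
    pi_hat order; from each still-intact pair the member with the lower call
    rate is dropped (ties: lexicographically larger id).  The result leaves
    no flagged pair with both members retained.
    """
    call = dict(zip(genotypes.samples["sample_id"],
                    genotypes.sample_call_rate()))
    flagged = [e for e in estimates
               if e.pi_hat >= thresholds.pihat_relatedness_min]
    flagged.sort(key=lambda e: (-e.pi_hat, e.sample_pair))
    excluded: dict[str, float] = {}
    for e in flagged:
        a, b = e.sample_pair
        if a in excluded or b in excluded:
            continue
        ca, cb = call.get(a, np.nan), call.get(b, np.nan)
        if ca < cb:
            drop = a
        elif cb < ca:
            drop = b
        else:
            drop = max(a, b)
        excluded[drop] = e.pi_hat
    return pd.DataFrame(
        {
            "sample_id": list(excluded.keys()),
            "reason": "related",
            "value": list(excluded.values()),
            "threshold": thresholds.pihat_relatedness_min,
        }
    )


# ---------------------------------------------------------------------------
# LD pruning and PCA ancestry outliers
# ---------------------------------------------------------------------------

def _imputed_dosage(genotypes: GenotypeMatrix) -> np.ndarray:
    g = genotypes.genotypes.astype(float)
    g[g == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(mean, inds[1])
    return g


def ld_prune(
    genotypes: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Sliding-window genotype-correlation pruning; returns a keep mask."""
    g = _imputed_dosage(genotypes)
    m = genotypes.n_snps
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        stop = min(start + window, m)
        idx = np.arange(start, stop)[keep[start:stop]]
        if len(idx) > 1:
            sub = g[:, idx]
            sd = sub.std(axis=0)
            valid = sd > 0
            if valid.sum() > 1:
                r = np.corrcoef(sub[:, valid].T)
                r2 = r**2
                vi = idx[valid]
                for a in range(len(vi)):
                    if not keep[vi[a]]:
                        continue
                    for b in range(a + 1, len(vi)):
                        if keep[vi[b]] and r2[a, b] > r2_max:
                            keep[vi[b]] = False
        if stop == m:
            break
        start += step
    return keep


def pca_ancestry_outliers(
    genotypes: GenotypeMatrix,
    reference_panel: GenotypeMatrix | None = None,
    thresholds: QcThresholds = QcThresholds(),
    n_components: int = 10,
    prune: bool = True,
    min_overlap: int = 1000,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Principal components of the standardised genotypes plus outlier flags.

    A study sample is an outlier when its distance from the study-cluster
    centroid on PCs 1-2 (in per-PC SD units) exceeds ``pca_outlier_sd``.
    With a reference panel the PCA runs on the combined matrix (shared SNPs
    only); without one it runs on the study alone, with a warning.
    """
    warnings: list[str] = []
    study = genotypes
    if reference_panel is not None:
        shared = pd.Index(study.snps["snp_id"]).intersection(
            reference_panel.snps["snp_id"])
        if len(shared) < min_overlap:
            raise SlepipeError(
                f"only {len(shared)} SNPs overlap the reference panel "
                f"(need >= {min_overlap})")
        si = [study.snp_index(s) for s in shared]
        ri = [reference_panel.snp_index(s) for s in shared]
        study_sub = study.subset(snp_mask=si)
        ref_sub = reference_panel.subset(snp_mask=ri)
        combined = np.vstack([_imputed_dosage(study_sub), _imputed_dosage(ref_sub)])
        n_study = study.n_samples
        sample_ids = (study.samples["sample_id"].tolist()
                      + reference_panel.samples["sample_id"].tolist())
        snp_keep_src = study_sub
    else:
        warnings.append("no reference panel supplied; PCA on study samples only")
        combined = _imputed_dosage(study)
        n_study = study.n_samples
        sample_ids = study.samples["sample_id"].tolist()
        snp_keep_src = study

    if prune:
        keep = ld_prune(snp_keep_src)
        combined = combined[:, keep]
    sd = combined.std(axis=0)
    use = sd > 0
    z = (combined[:, use] - combined[:, use].mean(axis=0)) / sd[use]
    k = min(n_components, min(z.shape) - 1)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    coords = pd.DataFrame(
        pcs, columns=[f"PC{i+1}" for i in range(k)])
    coords.insert(0, "sample_id", sample_ids)
    coords["panel"] = ["study"] * n_study + ["reference"] * (len(sample_ids) - n_study)

    study_pcs = pcs[:n_study, :2]
    centroid = np.median(study_pcs, axis=0)
    spread = study_pcs.std(axis=0)
    spread[spread == 0] = 1.0
    dist = np.sqrt((((study_pcs - centroid) / spread) ** 2).sum(axis=1))
    outliers = dist > thresholds.pca_outlier_sd
    return coords, outliers, warnings


# ---------------------------------------------------------------------------
# genomic control
# ---------------------------------------------------------------------------

def lambda_gc(chi2_values: np.ndarray) -> float:
    """Genomic-control inflation factor: median chi-square over its null median."""
    x = np.asarray(chi2_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise SlepipeError("lambda_gc needs at least one finite statistic")
    return float(np.median(x) / CHI2_1DF_MEDIAN)


def qq_plot(p_values: np.ndarray, ax=None):
    """Quantile-quantile plot of -log10 P against the uniform expectation."""
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(np.clip(p, 1e-300, 1.0))
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(exp, obs, ".", ms=3)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("expected $-\\log_{10} P$")
    ax.set_ylabel("observed $-\\log_{10} P$")
    return ax


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _append_rows(base: pd.DataFrame, extra: pd.DataFrame) -> pd.DataFrame:
    if base.empty:
        return extra.reset_index(drop=True)
    return pd.concat([base, extra], ignore_index=True)


def run_qc(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    check_relatedness: bool = False,
    reference_panel: GenotypeMatrix | None = None,
    check_ancestry: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the full QC battery and return the retained panel plus report.

    Sample call-rate and SNP filters alternate until a fixed point (removing
    SNPs can change sample call rates and vice versa), which makes the whole
    procedure idempotent.  Relatedness and ancestry scans are opt-in because
    they are quadratic / SVD-sized.
    """
    report = QcReport()
    retained = genotypes
    for _ in range(10):
        srep = filter_samples_by_call_rate(retained, thresholds)
        bad_samples = set(srep.excluded_samples["sample_id"])
        if bad_samples:
            report.excluded_samples = _append_rows(
                report.excluded_samples, srep.excluded_samples)
            retained = retained.subset(
                sample_mask=~retained.samples["sample_id"].isin(
                    bad_samples).to_numpy())
        nrep = filter_snps(retained, thresholds)
        bad_snps = set(nrep.excluded_snps["snp_id"])
        if bad_snps:
            report.excluded_snps = _append_rows(
                report.excluded_snps, nrep.excluded_snps)
            retained = retained.subset(
                snp_mask=~retained.snps["snp_id"].isin(bad_snps).to_numpy())
        if not bad_samples and not bad_snps:
            break

    if check_relatedness:
        keep = ld_prune(retained)
        pruned = retained.subset(snp_mask=keep)
        freqs = pruned.allele1_freq()
        ests = []
        for i in range(pruned.n_samples):
            for j in range(i + 1, pruned.n_samples):
                ests.append(estimate_ibd(pruned, (i, j), freqs))
        rel = flag_related_pairs(ests, retained, thresholds)
        if len(rel):
            report.excluded_samples = _append_rows(
                report.excluded_samples, rel)
            retained = retained.subset(
                sample_mask=~retained.samples["sample_id"].isin(
                    set(rel["sample_id"])).to_numpy())

    if check_ancestry:
        coords, outliers, _ = pca_ancestry_outliers(
            retained, reference_panel, thresholds)
        report.pca_coordinates = coords
        if outliers.any():
            out_ids = retained.samples.loc[outliers, "sample_id"]
            report.excluded_samples = _append_rows(
                report.excluded_samples,
                pd.DataFrame({"sample_id": out_ids, "reason": "pca_outlier",
                              "value": np.nan,
                              "threshold": thresholds.pca_outlier_sd}))
            retained = retained.subset(sample_mask=~outliers)

    if check_relatedness or check_ancestry:
        # sample removals can shift SNP statistics; re-filter once more
        snp_report = filter_snps(retained, thresholds)
        bad_snps = set(snp_report.excluded_snps["snp_id"])
        if bad_snps:
            report.excluded_snps = _append_rows(
                report.excluded_snps, snp_report.excluded_snps)
            retained = retained.subset(
                snp_mask=~retained.snps["snp_id"].isin(bad_snps).to_numpy())
    return retained, report
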