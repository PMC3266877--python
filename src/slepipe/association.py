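"""Case-control association: trend tests, allelic odds ratios, meta-analysis.

Per-stage inference uses the 1-df Cochran-Armitage trend test on genotype
counts and the allelic odds ratio with a Woolf (log-OR normal) confidence
interval.  Stages are combined with the Mantel-Haenszel fixed-effect
estimator over per-stage allele 2x2 tables, with the Robins-Breslow-Greenland
variance for the interval and the 1-df Mantel-Haenszel chi-square (no
continuity correction) for the combined P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .containers import GenotypeCounts, GenotypeMatrix, SlepipeError

__all__ = [
    "CaseControl2x3",
    "AlleleTable2x2",
    "AssociationResult",
    "MetaResult",
    "cochran_armitage_trend",
    "allelic_odds_ratio",
    "allele_counts_from_freq",
    "mantel_haenszel",
    "stage_association_scan",
    "replication_count",
    "GENOME_WIDE_P",
]

#: Conventional genome-wide significance threshold.
GENOME_WIDE_P = 5.0e-8


@dataclass
class CaseControl2x3:
    """Genotype count rows for cases and controls at one SNP."""

    case: GenotypeCounts
    control: GenotypeCounts

    def __post_init__(self) -> None:
        if self.case.n_called == 0 or self.control.n_called == 0:
            raise ValueError("both rows must contain called genotypes")


@dataclass
class AlleleTable2x2:
    """Allele-count 2x2 table for one SNP in one stage (a,b | c,d layout)."""

    case_allele1: float
    case_allele2: float
    control_allele1: float
    control_allele2: float
    stage_label: str = ""

    def __post_init__(self) -> None:
        cells = (self.case_allele1, self.case_allele2,
                 self.control_allele1, self.control_allele2)
        if any(c < 0 for c in cells):
            raise ValueError("allele counts must be non-negative")
        if self.case_allele1 + self.case_allele2 <= 0:
            raise ValueError("empty case row")
        if self.control_allele1 + self.control_allele2 <= 0:
            raise ValueError("empty control row")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.case_allele1, self.case_allele2,
                self.control_allele1, self.control_allele2)

    @classmethod
    def from_genotype_counts(cls, case: GenotypeCounts, control: GenotypeCounts,
                             stage_label: str = "") -> "AlleleTable2x2":
        return cls(case.allele1_count, 2 * case.n_called - case.allele1_count,
                   control.allele1_count,
                   2 * control.n_called - control.allele1_count, stage_label)

    @classmethod
    def from_frequencies(cls, freq_case: float, freq_control: float,
                         n_case: int, n_control: int,
                         stage_label: str = "") -> "AlleleTable2x2":
        a, b = allele_counts_from_freq(freq_case, n_case)
        c, d = allele_counts_from_freq(freq_control, n_control)
        return cls(a, b, c, d, stage_label)


@dataclass
class AssociationResult:
    """Single-SNP, single-stage association summary."""

    snp_id: str
    freq_case: float
    freq_control: float
    or_point: float
    ci95: tuple[float, float]
    chi2_trend: float
    p_value: float
    continuity_corrected: bool = False


@dataclass
class MetaResult:
    """Mantel-Haenszel combination across stages."""

    snp_id: str
    or_mh: float
    ci95: tuple[float, float]
    p_combined: float
    chi2_mh: float
    n_strata: int


# ---------------------------------------------------------------------------
# trend test
# ---------------------------------------------------------------------------

def _trend_chi2(r: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Vectorised Cochran-Armitage chi-square with scores (0, 1, 2).

    ``r`` and ``s`` are (..., 3) genotype count arrays for cases and
    controls.  Monomorphic tables (zero score variance) return 0.
    """
    w = np.array([0.0, 1.0, 2.0])
    n = r + s
    N = n.sum(axis=-1)
    R = r.sum(axis=-1)
    swr = (w * r).sum(axis=-1)
    swn = (w * n).sum(axis=-1)
    sw2n = (w**2 * n).sum(axis=-1)
    num = N * (N * swr - R * swn) ** 2
    den = R * (N - R) * (N * sw2n - swn**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    return out


def cochran_armitage_trend(table: CaseControl2x3) -> tuple[float, float]:
    """Cochran-Armitage trend statistic and its 1-df upper-tail P."""
    r = np.array([table.case.n_hom_ref, table.case.n_het, table.case.n_hom_alt],
                 dtype=float)
    s = np.array([table.control.n_hom_ref, table.control.n_het,
                  table.control.n_hom_alt], dtype=float)
    x = float(_trend_chi2(r, s))
    return x, float(chi2.sf(x, 1)) if x > 0 else 1.0


# ---------------------------------------------------------------------------
# allelic odds ratio
# ---------------------------------------------------------------------------

def allele_counts_from_freq(freq: float, n_subjects: int) -> tuple[int, int]:
    """Allele counts from a (possibly rounded) printed frequency.

    Allele-1 count is ``2 n * freq`` rounded half away from zero, the
    convention used when re-deriving counts from published tables.
    """
    if not (0.0 < freq < 1.0):
        raise ValueError("frequency must be in (0, 1)")
    if n_subjects <= 0:
        raise ValueError("n_subjects must be > 0")
    a = int(math.floor(2 * n_subjects * freq + 0.5))
    return a, 2 * n_subjects - a


def _woolf_ci(a: float, b: float, c: float, d: float,
              level: float = 0.95) -> tuple[float, float, float, bool]:
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2)
    lo, hi = math.exp(math.log(or_point) - z * se), math.exp(
        math.log(or_point) + z * se)
    return or_point, lo, hi, corrected


def allelic_odds_ratio(
    freq_case: float, freq_control: float, n_case: int, n_control: int,
    snp_id: str = "",
) -> AssociationResult:
    """Allelic OR with Woolf 95% CI from frequencies and subject counts.

    Counts are reconstructed with :func:`allele_counts_from_freq`; a zero
    cell triggers the 0.5 continuity correction and sets the flag.
    """
    a, b = allele_counts_from_freq(freq_case, n_case)
    c, d = allele_counts_from_freq(freq_control, n_control)
    or_point, lo, hi, corrected = _woolf_ci(a, b, c, d)
    return AssociationResult(
        snp_id=snp_id, freq_case=freq_case, freq_control=freq_control,
        or_point=or_point, ci95=(lo, hi), chi2_trend=np.nan, p_value=np.nan,
        continuity_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Mantel-Haenszel combination
# ---------------------------------------------------------------------------

def mantel_haenszel(strata: list[AlleleTable2x2], snp_id: str = "") -> MetaResult:
    """Fixed-effect Mantel-Haenszel OR, RBG 95% CI and 1-df chi-square P.

    Strata whose total is too small to contribute (N <= 1) are skipped;
    raises if every stratum is degenerate.
    """
    if not strata:
        raise SlepipeError("mantel_haenszel requires at least one stratum")
    R = S = 0.0
    sum_pr = sum_psqr = sum_qs = 0.0
    num = var = 0.0
    used = 0
    for t in strata:
        a, b, c, d = t.cells
        N = a + b + c + d
        if N <= 1:
            continue
        used += 1
        Ri, Si = a * d / N, b * c / N
        Pi, Qi = (a + d) / N, (b + c) / N
        R += Ri
        S += Si
        sum_pr += Pi * Ri
        sum_psqr += Pi * Si + Qi * Ri
        sum_qs += Qi * Si
        num += a - (a + b) * (a + c) / N
        var += (a + b) * (c + d) * (a + c) * (b + d) / (N**2 * (N - 1))
    if used == 0 or S == 0 or R == 0:
        raise SlepipeError("all strata degenerate in Mantel-Haenszel")
    or_mh = R / S
    var_log = (sum_pr / (2 * R**2) + sum_psqr / (2 * R * S)
               + sum_qs / (2 * S**2))
    z = norm.ppf(0.975)
    lo = math.exp(math.log(or_mh) - z * math.sqrt(var_log))
    hi = math.exp(math.log(or_mh) + z * math.sqrt(var_log))
    x = num**2 / var if var > 0 else 0.0
    p = float(chi2.sf(x, 1)) if x > 0 else 1.0
    return MetaResult(snp_id=snp_id, or_mh=or_mh, ci95=(lo, hi),
                      p_combined=p, chi2_mh=x, n_strata=used)


# ---------------------------------------------------------------------------
# genome-wide scan
# ---------------------------------------------------------------------------

def stage_association_scan(
    genotypes: GenotypeMatrix,
    stage: str | None = None,
    significance_p: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """One association row per SNP for a labelled case-control panel.

    Missing genotypes are dropped per SNP (complete-case).  Returns a
    DataFrame with frequencies, allelic OR/CI, trend chi-square, P and the
    genome-wide significance flag.
    """
    case_mask = genotypes.case_mask
    ctrl_mask = genotypes.control_mask
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise SlepipeError("scan requires both cases and controls")
    g = genotypes.genotypes
    r = np.stack([(g[case_mask] == k).sum(axis=0) for k in range(3)],
                 axis=1).astype(float)
    s = np.stack([(g[ctrl_mask] == k).sum(axis=0) for k in range(3)],
                 axis=1).astype(float)
    x = _trend_chi2(r, s)
    p = np.where(x > 0, chi2.sf(x, 1), 1.0)

    a = 2 * r[:, 2] + r[:, 1]
    b = 2 * r[:, 0] + r[:, 1]
    c = 2 * s[:, 2] + s[:, 1]
    d = 2 * s[:, 0] + s[:, 1]
    nc = r.sum(axis=1)
    nk = s.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_case = a / (2 * nc)
        freq_ctrl = c / (2 * nk)
    zero = np.minimum.reduce([a, b, c, d]) == 0
    aa = np.where(zero, a + 0.5, a)
    bb = np.where(zero, b + 0.5, b)
    cc = np.where(zero, c + 0.5, c)
    dd = np.where(zero, d + 0.5, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        orr = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        zq = norm.ppf(0.975)
        lo = np.exp(np.log(orr) - zq * se)
        hi = np.exp(np.log(orr) + zq * se)

    out = genotypes.snps[["snp_id", "chrom", "pos", "allele1", "allele2"]].copy()
    out["stage"] = stage if stage is not None else (
        genotypes.samples["stage"].iloc[0] if len(genotypes.samples) else "")
    out["n_case"] = nc.astype(int)
    out["n_control"] = nk.astype(int)
    out["freq_case"] = freq_case
    out["freq_control"] = freq_ctrl
    out["or"] = orr
    out["ci_low"] = lo
    out["ci_high"] = hi
    out["chi2"] = x
    out["p"] = p
    out["significant"] = p < significance_p
    return out


def replication_count(
    p_values: pd.Series | np.ndarray,
    alpha: float = 0.01,
    categories: pd.Series | np.ndarray | None = None,
) -> tuple[int, dict[str, tuple[int, int, float]]]:
    """Count loci replicating at ``alpha``; optionally per-category rates.

    Missing P-values are skipped (with those loci excluded from totals).
    Per-category output maps label -> (replicated, total, proportion).
    """
    p = pd.Series(np.asarray(p_values, dtype=float))
    ok = p.notna()
    hits = (p < alpha) & ok
    per_category: dict[str, tuple[int, int, float]] = {}
    if categories is not None:
        cats = pd.Series(categories).reset_index(drop=True)
        for label in cats.dropna().unique():
            mask = (cats == label) & ok.reset_index(drop=True)
            n = int(mask.sum())
            k = int((hits.reset_index(drop=True) & mask).sum())
            per_category[str(label)] = (k, n, k / n if n else float("nan"))
    return int(hits.sum()), per_category
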