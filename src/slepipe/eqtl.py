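"""Cis-eQTL mapping and FDR-based positivity flags.

SNP-probe pairs are formed when a probe interval intersects the SNP-centred
cis window (default +/-300 kb, boundaries inclusive).  Expression is
rank-based inverse-normal transformed per probe, each pair is tested by
ordinary least squares of expression on the 0/1/2 genotype dosage, and
Benjamini-Hochberg q-values are computed over one global family.  A SNP is
"eQTL positive" when its best cis q-value falls below the threshold
(default 0.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm
from scipy.stats import t as t_dist

from .containers import (
    MISSING,
    ExpressionMatrix,
    GenotypeMatrix,
    ProbeAnnotation,
    SlepipeError,
)

__all__ = [
    "EqtlTest",
    "map_cis_pairs",
    "normalize_expression",
    "eqtl_regression",
    "bh_fdr",
    "eqtl_scan",
    "flag_eqtl_positive",
    "positivity_enrichment",
    "CIS_WINDOW_BP",
    "Q_THRESHOLD",
]

CIS_WINDOW_BP = 300_000
Q_THRESHOLD = 0.2


@dataclass
class EqtlTest:
    """One SNP-probe additive regression."""

    snp_id: str
    probe_id: str
    beta: float
    se: float
    r_squared: float
    p: float
    n: int
    q: float = float("nan")


# ---------------------------------------------------------------------------
# cis pairing
# ---------------------------------------------------------------------------

def map_cis_pairs(
    snps: pd.DataFrame,
    probes: ProbeAnnotation,
    window_bp: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """SNP-probe pairs whose probe interval intersects the cis window.

    The window is ``[pos - window_bp, pos + window_bp]`` in 1-based
    coordinates, boundaries inclusive; probe intervals are BED 0-based
    half-open and converted at this boundary.  Chromosome mismatches are
    simply not paired.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    out = []
    ptab = probes.table
    for chrom, snp_grp in snps.groupby("chrom"):
        pgrp = ptab[ptab["chrom"] == chrom]
        if pgrp.empty:
            continue
        first = pgrp["start"].to_numpy() + 1  # 1-based first base of probe
        last = pgrp["end"].to_numpy()         # 1-based last base
        for _, srow in snp_grp.iterrows():
            lo, hi = srow["pos"] - window_bp, srow["pos"] + window_bp
            hit = (first <= hi) & (last >= lo)
            for pid in pgrp.loc[hit, "probe_id"]:
                out.append((srow["snp_id"], pid))
    return pd.DataFrame(out, columns=["snp_id", "probe_id"])


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize_expression(
    raw: ExpressionMatrix,
) -> tuple[ExpressionMatrix, list[str]]:
    """Per-probe rank-based inverse-normal transform across individuals.

    Ties get average ranks; ranks map through the Blom offset
    ``(r - 3/8) / (n + 1/4)`` into normal quantiles, giving per-probe mean
    ~0 and variance ~1.  Constant probes become all-zero and are returned
    in the flag list.
    """
    if raw.values.shape[1] < 2:
        raise SlepipeError("normalisation needs at least two samples")
    vals = raw.values.to_numpy(dtype=float)
    n = vals.shape[1]
    flagged: list[str] = []
    out = np.zeros_like(vals)
    for i, probe in enumerate(raw.values.index):
        row = vals[i]
        if np.nanstd(row) == 0:
            flagged.append(str(probe))
            continue
        ranks = pd.Series(row).rank(method="average").to_numpy()
        out[i] = norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    frame = pd.DataFrame(out, index=raw.values.index, columns=raw.values.columns)
    return ExpressionMatrix(frame), flagged


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def eqtl_regression(
    genotype_vector: np.ndarray, expression_vector: np.ndarray,
    snp_id: str = "", probe_id: str = "",
) -> EqtlTest:
    """OLS of expression on additive genotype dosage for one pair.

    Complete-case over the pair; two-sided t-test on the slope;
    ``r_squared`` is the squared sample correlation.
    """
    g = np.asarray(genotype_vector, dtype=float)
    y = np.asarray(expression_vector, dtype=float)
    ok = (g != MISSING) & np.isfinite(g) & np.isfinite(y)
    g, y = g[ok], y[ok]
    n = len(g)
    if n < 3:
        raise SlepipeError("eQTL regression needs >= 3 complete pairs")
    sxx = float(np.sum((g - g.mean()) ** 2))
    if sxx == 0:
        raise SlepipeError("monomorphic in expression panel")
    sxy = float(np.sum((g - g.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    beta = sxy / sxx
    rss = syy - beta * sxy
    if n > 2 and rss > 0:
        sigma2 = rss / (n - 2)
        se = math.sqrt(sigma2 / sxx)
        tval = beta / se
        p = float(2 * t_dist.sf(abs(tval), n - 2))
    else:
        se, p = 0.0, 0.0 if beta != 0 else 1.0
    r2 = (sxy**2 / (sxx * syy)) if syy > 0 else 0.0
    return EqtlTest(snp_id=snp_id, probe_id=probe_id, beta=beta, se=se,
                    r_squared=r2, p=p, n=n)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# scan + flags
# ---------------------------------------------------------------------------

def eqtl_scan(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    probes: ProbeAnnotation,
    window_bp: int = CIS_WINDOW_BP,
    normalize: bool = True,
) -> pd.DataFrame:
    """Test every cis SNP-probe pair; returns the pair-level table with q.

    Expression samples are matched to genotype samples by id (the
    intersection, in genotype order).  Q-values come from one global BH
    family over all tested pairs.
    """
    expr = expression
    if normalize:
        expr, _ = normalize_expression(expression)
    shared = [s for s in genotypes.samples["sample_id"] if s in set(expr.sample_ids)]
    if len(shared) < 3:
        raise SlepipeError("fewer than 3 samples shared between panels")
    gidx = [genotypes.samples.index[genotypes.samples["sample_id"] == s][0]
            for s in shared]
    gsub = genotypes.genotypes[gidx]
    esub = expr.values[shared]

    pairs = map_cis_pairs(genotypes.snps, probes, window_bp)
    rows = []
    snp_col = {s: j for j, s in enumerate(genotypes.snps["snp_id"])}
    for snp_id, probe_id in pairs.itertuples(index=False):
        g = gsub[:, snp_col[snp_id]]
        y = esub.loc[probe_id].to_numpy()
        try:
            t = eqtl_regression(g, y, snp_id=snp_id, probe_id=probe_id)
        except SlepipeError:
            continue
        rows.append((snp_id, probe_id, t.beta, t.se, t.r_squared, t.p, t.n))
    table = pd.DataFrame(
        rows, columns=["snp_id", "probe_id", "beta", "se", "r2", "p", "n"])
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table


def flag_eqtl_positive(
    tests: pd.DataFrame,
    all_snp_ids: pd.Series | list[str],
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-SNP positivity: min cis q-value strictly below the threshold.

    SNPs without any tested cis probe are negative with no best probe.
    """
    flags = pd.DataFrame({"snp_id": list(all_snp_ids)})
    if len(tests):
        best = tests.sort_values(["q", "p"]).groupby("snp_id").first()
        flags = flags.merge(
            best[["probe_id", "q"]].rename(
                columns={"probe_id": "best_probe", "q": "best_q"}),
            left_on="snp_id", right_index=True, how="left")
    else:
        flags["best_probe"] = None
        flags["best_q"] = np.nan
    flags["positive"] = flags["best_q"] < q_threshold
    flags["positive"] = flags["positive"].fillna(False).astype(bool)
    return flags


def positivity_enrichment(
    flags: pd.DataFrame,
    focal_snp_set: set[str] | list[str],
    background_snp_set: set[str] | list[str],
) -> tuple[float, float, float]:
    """Positivity rates in a focal vs background SNP set, with Fisher P.

    Returns ``(rate_focal, rate_background, fisher_p)``; the two-sided
    Fisher exact test on the 2x2 of positive/negative by set is a
    supplementary diagnostic.
    """
    focal = set(focal_snp_set)
    background = set(background_snp_set)
    if not focal or not background:
        raise SlepipeError("both SNP sets must be nonempty")
    fl = flags.set_index("snp_id")["positive"]
    missing = (focal | background) - set(fl.index)
    if missing:
        raise SlepipeError(f"flags missing for {sorted(missing)[:5]} ...")
    kf = int(fl.loc[list(focal)].sum())
    kb = int(fl.loc[list(background)].sum())
    nf, nb = len(focal), len(background)
    _, p = fisher_exact([[kf, nf - kf], [kb, nb - kb]], alternative="two-sided")
    return kf / nf, kb / nb, float(p)
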