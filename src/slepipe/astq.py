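"""Allele-specific transcript quantification from allele-discriminating qPCR.

A heterozygote's two alleles are amplified with channel-specific probes
(VIC/FAM).  Because Ct falls by one cycle per doubling of template, the
replicate-mean Ct difference dCt = Ct(VIC) - Ct(FAM) is linear in the log2
allelic ratio; a genomic-DNA mixture series with known ratios calibrates
that line (slope -1 under perfect efficiency, intercept absorbing the
probe-specific offset).  Sample dCt values are inverted through the curve
into allelic ratios, each line's cDNA ratio is normalised by its own
genomic-DNA ratio, and allelic imbalance across lines is tested with a
paired t-test on log2 ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import ttest_rel

from .containers import SlepipeError
from .synthetic import AstqPlate

__all__ = [
    "StandardCurve",
    "AllelicRatioResult",
    "build_standard_curve",
    "quantify_allelic_ratio",
    "allelic_imbalance_test",
    "relative_expression",
]


@dataclass
class StandardCurve:
    """Least-squares line of mean dCt on log2 allelic ratio."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class AllelicRatioResult:
    """Per-line allelic ratios: genomic DNA, cDNA, and their quotient."""

    sample_id: str
    ratio_dna: float
    ratio_cdna: float

    @property
    def ratio_normalized(self) -> float:
        return self.ratio_cdna / self.ratio_dna


def build_standard_curve(mixtures: list[AstqPlate]) -> StandardCurve:
    """Fit the calibration line from the genomic-DNA mixture series.

    Uses replicate-mean dCt per mixture against log2(mixture ratio).
    Requires at least three distinct ratios.
    """
    ratios = [m.mixture_ratio for m in mixtures if m.material == "mixture"]
    dcts = [m.delta_ct for m in mixtures if m.material == "mixture"]
    if len(set(ratios)) < 3:
        raise SlepipeError("standard curve needs >= 3 distinct mixture ratios")
    x = np.log2(np.asarray(ratios, dtype=float))
    y = np.asarray(dcts, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept),
                         r_squared=r2, n_points=len(ratios))


def quantify_allelic_ratio(
    sample: AstqPlate, curve: StandardCurve,
) -> tuple[float, float]:
    """Invert a sample's mean dCt through the curve into an allelic ratio.

    Returns ``(ratio, se)`` where the standard error propagates replicate
    Ct variability to the ratio scale (first order).
    """
    if abs(curve.slope) < 0.2:
        raise SlepipeError("uninformative curve: |slope| < 0.2")
    dct = sample.delta_ct
    log2_ratio = (dct - curve.intercept) / curve.slope
    ratio = 2.0 ** log2_ratio
    nv, nf = sample.ct_vic.size, sample.ct_fam.size
    var_dct = (sample.ct_vic.var(ddof=1) / nv if nv > 1 else 0.0) \
        + (sample.ct_fam.var(ddof=1) / nf if nf > 1 else 0.0)
    # d ratio / d dct = ratio * ln2 / slope
    se = abs(ratio * math.log(2.0) / curve.slope) * math.sqrt(var_dct)
    return float(ratio), float(se)


def allelic_imbalance_test(
    results: list[AllelicRatioResult],
) -> tuple[float, float, float]:
    """Paired t-test of cDNA vs genomic-DNA allelic ratios across lines.

    The test operates on per-line log2(cDNA ratio) - log2(DNA ratio)
    differences; the back-transformed geometric means are reported.
    Returns ``(mean_cdna_ratio, mean_dna_ratio, p)``.
    """
    if len(results) < 2:
        raise SlepipeError("imbalance test needs >= 2 lines")
    log_c = np.log2([r.ratio_cdna for r in results])
    log_d = np.log2([r.ratio_dna for r in results])
    mean_c = float(2.0 ** log_c.mean())
    mean_d = float(2.0 ** log_d.mean())
    diffs = log_c - log_d
    if np.allclose(diffs, diffs[0]) and abs(diffs[0]) < 1e-12:
        return mean_c, mean_d, 1.0
    if np.allclose(diffs, diffs[0]):
        # zero variance with nonzero shift: the paired t is degenerate
        return mean_c, mean_d, 0.0
    _, p = ttest_rel(log_c, log_d)
    return mean_c, mean_d, float(p)


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Reference-normalised expression by the dCt method: 2^-(Ct_t - Ct_r)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(ct_target - ct_reference)))


def quantify_experiment(
    mixtures: list[AstqPlate],
    dna: list[AstqPlate],
    cdna: list[AstqPlate],
) -> tuple[StandardCurve, list[AllelicRatioResult], list[str]]:
    """Full ASTQ reduction: fit the curve and pair each line's DNA/cDNA.

    Lines present on only one material are excluded with a warning entry.
    """
    curve = build_standard_curve(mixtures)
    dna_by_id = {p.sample_id: p for p in dna}
    cdna_by_id = {p.sample_id: p for p in cdna}
    warnings: list[str] = []
    results: list[AllelicRatioResult] = []
    for sid in dna_by_id:
        if sid not in cdna_by_id:
            warnings.append(f"unpaired genomic DNA sample {sid} excluded")
            continue
        r_dna, _ = quantify_allelic_ratio(dna_by_id[sid], curve)
        r_cdna, _ = quantify_allelic_ratio(cdna_by_id[sid], curve)
        results.append(AllelicRatioResult(sid, r_dna, r_cdna))
    for sid in cdna_by_id:
        if sid not in dna_by_id:
            warnings.append(f"unpaired cDNA sample {sid} excluded")
    return curve, results, warnings
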