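"""Synthetic cohort, expression, pooled-scan and qPCR data generators.

The generators emulate the statistical structure a staged case-control GWAS
with eQTL prioritization assumes:

* biallelic SNPs organised in LD blocks, built from finite per-block
  haplotype pools so that r²/D' oracles can be computed by direct
  haplotype counting on the emitted pool draws;
* case-control ascertainment under an additive logistic liability model,
  with the baseline logit solved so the population prevalence matches the
  configured value;
* probe-level expression with additive per-allele genotype effects plus
  Gaussian noise, and decoy probes with no genotype dependence;
* a pooled-DNA scan summarised as per-SNP rank-based P values, uniform under
  the null and enriched near causal loci;
* allele-discriminating qPCR plates obeying the log2 template-amount / Ct
  relationship, including the genomic-DNA mixture series used for standard
  curves.

One master seed drives everything; per-component streams are spawned from a
``numpy.random.SeedSequence`` in a fixed order, so identical configurations
yield byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .containers import (
    CASE,
    CONTROL,
    MISSING,
    ConfigurationError,
    ExpressionMatrix,
    GenotypeMatrix,
    ProbeAnnotation,
)

__all__ = [
    "RiskSnp",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "assign_phenotypes",
    "simulate_cohort",
    "simulate_expression",
    "simulate_pooled_scan",
    "simulate_astq_experiment",
    "AstqPlate",
    "AstqExperiment",
]

# Genome layout constants for the synthetic marker map.
_SNP_SPACING_BP = 5_000
_BLOCK_GAP_BP = 1_000_000
_N_CHROMS = 22


@dataclass(frozen=True)
class RiskSnp:
    """A configured causal SNP: disease odds ratio and optional cis-eQTL effect."""

    snp_index: int
    allele_or: float = 1.0
    eqtl_beta: float | None = None

    def __post_init__(self) -> None:
        if self.allele_or <= 0:
            raise ConfigurationError("allele_or must be > 0")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the discovery-stage design the pipeline targets: 891
    cases vs 3,384 controls, SNPs in LD blocks with strong within-block
    correlation, ~90 expression samples (a HapMap-scale lymphoblastoid
    panel) with about five probes per region.
    """

    n_cases: int = 891
    n_controls: int = 3384
    n_snps: int = 1000
    n_blocks: int = 100
    block_ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    risk_snps: tuple[RiskSnp, ...] = ()
    prevalence: float = 0.01
    n_expr_samples: int = 90
    probes_per_region: int = 5
    expr_noise_sd: float = 1.0
    missing_rate: float = 0.002
    seed: int = 0
    pool_size: int = 200
    pooled_enrichment: float = 4.0

    def __post_init__(self) -> None:
        self.risk_snps = tuple(
            rs if isinstance(rs, RiskSnp) else RiskSnp(*rs) for rs in self.risk_snps
        )
        for name in ("n_cases", "n_controls", "n_snps", "n_blocks",
                     "n_expr_samples", "probes_per_region", "pool_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0.0 <= self.block_ld_rho < 1.0):
            raise ConfigurationError("block_ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.expr_noise_sd < 0:
            raise ConfigurationError("expr_noise_sd must be >= 0")
        if self.n_blocks > self.n_snps:
            raise ConfigurationError("n_blocks cannot exceed n_snps")
        for rs in self.risk_snps:
            if not (0 <= rs.snp_index < self.n_snps):
                raise ConfigurationError(
                    f"risk_snps: snp_index {rs.snp_index} out of range")

    # -- seed bookkeeping ---------------------------------------------

    def seed_streams(self) -> dict[str, np.random.Generator]:
        """Deterministic per-component RNG streams spawned from the master seed."""
        names = ["pools", "cohort", "missing", "expression", "pooled_scan", "astq"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class SyntheticCohort:
    """A simulated case-control panel plus ground truth."""

    genotypes: GenotypeMatrix
    truth: pd.DataFrame  # snp_id, snp_index, allele_or, eqtl_beta, causal
    haplotype_pools: list[np.ndarray] = field(default_factory=list)
    block_of_snp: np.ndarray | None = None


# ---------------------------------------------------------------------------
# marker map and haplotype pools
# ---------------------------------------------------------------------------

def _block_sizes(n_snps: int, n_blocks: int) -> np.ndarray:
    sizes = np.full(n_blocks, n_snps // n_blocks, dtype=int)
    sizes[: n_snps % n_blocks] += 1
    return sizes


def _snp_map(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Lay blocks round-robin over 22 autosomes, 5 kb SNP spacing, 1 Mb gaps."""
    sizes = _block_sizes(config.n_snps, config.n_blocks)
    chroms, positions, block_of = [], [], []
    cursor = {c: 1_000_000 for c in range(1, _N_CHROMS + 1)}
    for b, size in enumerate(sizes):
        chrom = (b % _N_CHROMS) + 1
        start = cursor[chrom]
        for k in range(size):
            chroms.append(chrom)
            positions.append(start + k * _SNP_SPACING_BP)
            block_of.append(b)
        cursor[chrom] = start + size * _SNP_SPACING_BP + _BLOCK_GAP_BP
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:05d}" for i in range(config.n_snps)],
            "chrom": chroms,
            "pos": positions,
            "allele1": "A",
            "allele2": "G",
        }
    )
    return snps, np.asarray(block_of)


def _simulate_pools(config: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-block haplotype pools with first-order Markov allele correlation.

    Within a block, adjacent SNPs have haplotype-level correlation
    ``block_ld_rho``; allele-1 frequencies are drawn uniformly from
    ``maf_range``.  Genotypes downstream are sums of two pool draws.
    """
    lo, hi = config.maf_range
    pools: list[np.ndarray] = []
    for size in _block_sizes(config.n_snps, config.n_blocks):
        freqs = rng.uniform(lo, hi, size=size)
        pool = np.empty((config.pool_size, size), dtype=np.int8)
        pool[:, 0] = rng.random(config.pool_size) < freqs[0]
        for j in range(1, size):
            p_prev, p_cur = freqs[j - 1], freqs[j]
            cov = config.block_ld_rho * math.sqrt(
                p_prev * (1 - p_prev) * p_cur * (1 - p_cur))
            p11 = p_prev * p_cur + cov
            p11 = min(max(p11, max(0.0, p_prev + p_cur - 1.0)), min(p_prev, p_cur))
            cond1 = p11 / p_prev if p_prev > 0 else p_cur
            cond0 = (p_cur - p11) / (1 - p_prev) if p_prev < 1 else p_cur
            u = rng.random(config.pool_size)
            pool[:, j] = np.where(pool[:, j - 1] == 1, u < cond1, u < cond0)
        pools.append(pool)
    return pools


def _materialize(
    pools: list[np.ndarray], draws: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Genotypes (n x m) for block-pool index draws (each n x n_blocks)."""
    i1, i2 = draws
    cols = [pool[i1[:, b]] + pool[i2[:, b]] for b, pool in enumerate(pools)]
    return np.concatenate(cols, axis=1).astype(np.int8)


def _draw_indices(
    pools: list[np.ndarray], n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_blocks = len(pools)
    size = pools[0].shape[0]
    i1 = rng.integers(0, size, size=(n, n_blocks))
    i2 = rng.integers(0, size, size=(n, n_blocks))
    return i1, i2


def _apply_missing(
    g: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate > 0:
        mask = rng.random(g.shape) < rate
        g = g.copy()
        g[mask] = MISSING
    return g


def simulate_genotypes(
    config: SimulationConfig,
    n_samples: int | None = None,
    return_haplotypes: bool = False,
):
    """Simulate an unlabelled genotype panel from block haplotype pools.

    Parameters
    ----------
    config
        Validated simulation parameters.
    n_samples
        Panel size; defaults to ``n_cases + n_controls``.
    return_haplotypes
        Also return the per-sample haplotypes (two ``n x n_snps`` arrays),
        enabling exact haplotype-counting LD oracles.
    """
    streams = config.seed_streams()
    pools = _simulate_pools(config, streams["pools"])
    n = n_samples if n_samples is not None else config.n_cases + config.n_controls
    draws = _draw_indices(pools, n, streams["cohort"])
    g = _materialize(pools, draws)
    g = _apply_missing(g, config.missing_rate, streams["missing"])
    snps, block_of = _snp_map(config)
    samples = pd.DataFrame(
        {"sample_id": [f"S{i:06d}" for i in range(n)],
         "status": CONTROL, "stage": "unassigned"}
    )
    gm = GenotypeMatrix(g, snps, samples)
    if return_haplotypes:
        i1, i2 = draws
        h1 = np.concatenate([pool[i1[:, b]] for b, pool in enumerate(pools)], axis=1)
        h2 = np.concatenate([pool[i2[:, b]] for b, pool in enumerate(pools)], axis=1)
        return gm, (h1, h2)
    return gm


# ---------------------------------------------------------------------------
# liability model and ascertainment
# ---------------------------------------------------------------------------

def _pool_score_distribution(
    pools: list[np.ndarray], block_of: np.ndarray, risk: Sequence[RiskSnp]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the genetic score under random pool mating.

    Enumerates unordered pool-haplotype pairs per block carrying risk SNPs
    and convolves the per-block score atoms across blocks.
    """
    if not risk:
        return np.array([0.0]), np.array([1.0])
    by_block: dict[int, list[RiskSnp]] = {}
    offsets = np.concatenate([[0], np.cumsum([p.shape[1] for p in pools])])
    for rs in risk:
        b = int(block_of[rs.snp_index])
        by_block.setdefault(b, []).append(rs)
    values, probs = np.array([0.0]), np.array([1.0])
    for b, snps_in_block in by_block.items():
        pool = pools[b]
        cols = [rs.snp_index - offsets[b] for rs in snps_in_block]
        betas = np.array([math.log(rs.allele_or) for rs in snps_in_block])
        hap_scores = pool[:, cols] @ betas  # per-haplotype contribution
        pair_scores = hap_scores[:, None] + hap_scores[None, :]
        v, c = np.unique(np.round(pair_scores, 12), return_counts=True)
        p = c / c.sum()
        values = (values[:, None] + v[None, :]).ravel()
        probs = (probs[:, None] * p[None, :]).ravel()
        values, inv = np.unique(np.round(values, 12), return_inverse=True)
        probs = np.bincount(inv, weights=probs)
    return values, probs


def _solve_baseline(
    values: np.ndarray, probs: np.ndarray, prevalence: float
) -> float:
    """Baseline logit b0 with E[expit(b0 + score)] = prevalence, to 1e-8."""

    def f(b0: float) -> float:
        return float(np.sum(expit(b0 + values) * probs) - prevalence)

    return brentq(f, -60.0, 60.0, xtol=1e-8)


def assign_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticCohort:
    """Label an existing panel by the liability model and take exact quotas.

    Statuses are Bernoulli draws from ``expit(b0 + sum(log OR * dosage))``;
    the first ``n_cases`` cases and ``n_controls`` controls (input order) are
    retained.  Raises if the panel cannot fill a quota — callers simulating
    at realistic prevalence should prefer :func:`simulate_cohort`, which
    resamples until the quotas are met.
    """
    if config.n_cases <= 0 or config.n_controls <= 0:
        raise ConfigurationError("n_cases and n_controls must be > 0")
    rng = rng if rng is not None else config.seed_streams()["cohort"]
    g = genotypes.genotypes
    score = np.zeros(genotypes.n_samples)
    for rs in config.risk_snps:
        dose = g[:, rs.snp_index].astype(float)
        dose[dose == MISSING] = 0.0
        score += math.log(rs.allele_or) * dose
    # empirical baseline: prevalence over the provided panel
    uniq, inv = np.unique(np.round(score, 12), return_inverse=True)
    probs = np.bincount(inv) / len(score)
    b0 = _solve_baseline(uniq, probs, config.prevalence)
    is_case = rng.random(len(score)) < expit(b0 + score)
    case_idx = np.flatnonzero(is_case)[: config.n_cases]
    ctrl_idx = np.flatnonzero(~is_case)[: config.n_controls]
    if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
        raise ConfigurationError(
            "panel too small to fill case/control quotas at the configured "
            "prevalence; use simulate_cohort for ascertained sampling")
    keep = np.concatenate([case_idx, ctrl_idx])
    gm = genotypes.subset(sample_mask=keep)
    gm.samples["status"] = np.r_[
        np.full(config.n_cases, CASE), np.full(config.n_controls, CONTROL)]
    return SyntheticCohort(genotypes=gm, truth=_truth_table(gm.snps, config))


def _truth_table(snps: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {
            "snp_id": snps["snp_id"].iloc[rs.snp_index],
            "snp_index": rs.snp_index,
            "chrom": snps["chrom"].iloc[rs.snp_index],
            "pos": snps["pos"].iloc[rs.snp_index],
            "allele_or": rs.allele_or,
            "eqtl_beta": np.nan if rs.eqtl_beta is None else rs.eqtl_beta,
            "causal": True,
        }
        for rs in config.risk_snps
    ]
    cols = ["snp_id", "snp_index", "chrom", "pos", "allele_or", "eqtl_beta", "causal"]
    return pd.DataFrame(rows, columns=cols)


def simulate_cohort(
    config: SimulationConfig, stage: str = "gwas", max_batches: int = 10_000,
    substream: int = 0,
) -> SyntheticCohort:
    """Simulate a fully ascertained case-control cohort.

    Rejection sampling against the liability model: candidate subjects are
    drawn as block-pool haplotype indices (cheap), their disease status is
    sampled from the logistic liability, and genotypes are materialised only
    for the subjects retained to fill the case/control quotas exactly.

    ``substream`` selects an independent subject-level random stream while
    keeping the haplotype pools (hence the marker panel and its allele
    frequencies) fixed — replication cohorts genotyped on the same panel.
    """
    streams = config.seed_streams()
    if substream:
        extra = np.random.SeedSequence((config.seed, substream)).spawn(2)
        streams["cohort"] = np.random.default_rng(extra[0])
        streams["missing"] = np.random.default_rng(extra[1])
    pools = _simulate_pools(config, streams["pools"])
    snps, block_of = _snp_map(config)
    values, probs = _pool_score_distribution(pools, block_of, config.risk_snps)
    b0 = _solve_baseline(values, probs, config.prevalence)
    offsets = np.concatenate([[0], np.cumsum([p.shape[1] for p in pools])])

    rng = streams["cohort"]
    need_case, need_ctrl = config.n_cases, config.n_controls
    batch = max(4096, int(1.2 * need_case / config.prevalence / 8))
    kept_draws: list[tuple[np.ndarray, np.ndarray]] = []
    kept_status: list[np.ndarray] = []
    for _ in range(max_batches):
        if need_case <= 0 and need_ctrl <= 0:
            break
        i1, i2 = _draw_indices(pools, batch, rng)
        score = np.zeros(batch)
        for rs in config.risk_snps:
            b = int(block_of[rs.snp_index])
            col = rs.snp_index - offsets[b]
            dose = pools[b][i1[:, b], col] + pools[b][i2[:, b], col]
            score += math.log(rs.allele_or) * dose
        is_case = rng.random(batch) < expit(b0 + score)
        case_take = np.flatnonzero(is_case)[:need_case]
        ctrl_take = np.flatnonzero(~is_case)[:need_ctrl]
        take = np.concatenate([case_take, ctrl_take])
        kept_draws.append((i1[take], i2[take]))
        kept_status.append(
            np.r_[np.full(len(case_take), CASE), np.full(len(ctrl_take), CONTROL)])
        need_case -= len(case_take)
        need_ctrl -= len(ctrl_take)
    if need_case > 0 or need_ctrl > 0:
        raise ConfigurationError(
            "could not fill case/control quotas; prevalence unattainable")
    i1 = np.concatenate([d[0] for d in kept_draws])
    i2 = np.concatenate([d[1] for d in kept_draws])
    status = np.concatenate(kept_status)
    order = np.argsort(-status, kind="stable")  # cases first, draw order kept
    g = _materialize(pools, (i1[order], i2[order]))
    g = _apply_missing(g, config.missing_rate, streams["missing"])
    samples = pd.DataFrame(
        {"sample_id": [f"S{i:06d}" for i in range(len(status))],
         "status": status[order], "stage": stage}
    )
    gm = GenotypeMatrix(g, snps, samples)
    return SyntheticCohort(
        genotypes=gm, truth=_truth_table(snps, config),
        haplotype_pools=pools, block_of_snp=block_of,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_PROBE_LEN_BP = 50
_CIS_PLACEMENT_BP = 250_000  # keep causal probes well inside the 300 kb window


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[ExpressionMatrix, ProbeAnnotation]:
    """Probe expression for the first ``n_expr_samples`` subjects.

    Each risk SNP with an ``eqtl_beta`` gets one causal probe inside its cis
    window (expression = beta x dosage + noise) plus decoys; every LD block
    additionally receives ``probes_per_region`` pure-noise decoy probes so
    that non-causal SNPs are genuinely evaluated downstream.
    """
    if config.n_expr_samples > genotypes.n_samples:
        raise ConfigurationError("n_expr_samples exceeds available samples")
    rng = config.seed_streams()["expression"]
    n = config.n_expr_samples
    sub = genotypes.subset(sample_mask=np.arange(n))
    chrom_len = {
        int(c): int(p.max()) + 500_000
        for c, p in genotypes.snps.groupby("chrom")["pos"]
    }

    records: list[dict] = []
    values: list[np.ndarray] = []

    def _place_probe(chrom: int, pos: int, pid: str, gene: str, expr: np.ndarray):
        offset = int(rng.integers(-_CIS_PLACEMENT_BP, _CIS_PLACEMENT_BP + 1))
        start0 = pos + offset - 1  # 0-based
        end0 = start0 + _PROBE_LEN_BP
        if start0 < 0 or end0 > chrom_len[int(chrom)]:
            raise ConfigurationError(
                f"probe {pid} placed outside chromosome bounds")
        records.append({"probe_id": pid, "chrom": int(chrom),
                        "start": start0, "end": end0, "gene_label": gene})
        values.append(expr)

    # causal probes + local decoys around each eQTL risk SNP
    for k, rs in enumerate(config.risk_snps):
        if rs.eqtl_beta is None:
            continue
        row = genotypes.snps.iloc[rs.snp_index]
        dose = sub.genotypes[:, rs.snp_index].astype(float)
        dose[dose == MISSING] = np.nan
        fill = np.nanmean(dose) if np.any(np.isfinite(dose)) else 0.0
        noise = rng.normal(0.0, config.expr_noise_sd, size=n)
        expr = rs.eqtl_beta * np.nan_to_num(dose, nan=fill) + noise
        _place_probe(row["chrom"], row["pos"], f"probe_causal_{k:03d}",
                     f"gene_{rs.snp_index}", expr)
        for d in range(config.probes_per_region - 1):
            _place_probe(row["chrom"], row["pos"], f"probe_decoy_{k:03d}_{d}",
                         f"gene_{rs.snp_index}",
                         rng.normal(0.0, config.expr_noise_sd, size=n))

    # background decoys: probes_per_region per block, anchored at random SNPs
    sizes = _block_sizes(config.n_snps, config.n_blocks)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for b in range(config.n_blocks):
        anchors = rng.integers(offsets[b], offsets[b + 1],
                               size=config.probes_per_region)
        for d, j in enumerate(anchors):
            row = genotypes.snps.iloc[int(j)]
            _place_probe(row["chrom"], row["pos"], f"probe_bg_{b:04d}_{d}",
                         f"bg_{int(j)}",
                         rng.normal(0.0, config.expr_noise_sd, size=n))

    frame = pd.DataFrame(
        np.vstack(values), index=[r["probe_id"] for r in records],
        columns=sub.samples["sample_id"].tolist(),
    )
    frame.index.name = "probe_id"
    return ExpressionMatrix(frame), ProbeAnnotation(pd.DataFrame(records))


# ---------------------------------------------------------------------------
# pooled scan
# ---------------------------------------------------------------------------

_POOLED_SIGNAL_BP = 100_000
_POOLED_DECAY_BP = 50_000


def simulate_pooled_scan(
    truth: pd.DataFrame, snps: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Per-SNP rank-based P values emulating a pooled-DNA scan summary.

    Null scores are standard normal; SNPs within 100 kb of a causal locus
    receive a mean shift of ``pooled_enrichment`` decayed exponentially with
    distance.  Rank-based P = rank/N with rank 1 the most extreme score, so
    P is uniform on {1/N..1} under the null.  Pooled markers are re-labelled
    (different platform) but share the synthetic coordinate system.
    """
    from .prioritize import rank_based_p  # late import avoids a cycle

    rng = config.seed_streams()["pooled_scan"]
    scores = rng.normal(0.0, 1.0, size=len(snps))
    if len(truth):
        pos = snps["pos"].to_numpy()
        chrom = snps["chrom"].to_numpy()
        for _, row in truth.iterrows():
            d = np.abs(pos - row["pos"])
            near = (chrom == row["chrom"]) & (d <= _POOLED_SIGNAL_BP)
            scores[near] += config.pooled_enrichment * np.exp(
                -d[near] / _POOLED_DECAY_BP)
    return pd.DataFrame(
        {
            "snp_id": [f"pool_{s}" for s in snps["snp_id"]],
            "chrom": snps["chrom"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "rank_p": rank_based_p(scores),
        }
    )


# ---------------------------------------------------------------------------
# qPCR / ASTQ
# ---------------------------------------------------------------------------

#: Genomic-DNA mixture series used for the standard curve (VIC : FAM).
MIXTURE_SERIES: tuple[float, ...] = (2 / 8, 3 / 7, 4 / 6, 5 / 5, 6 / 4, 7 / 3, 8 / 2)


@dataclass
class AstqPlate:
    """Replicate Ct readings for one sample/material on the two channels."""

    sample_id: str
    material: str  # genomic_dna | cdna | mixture
    mixture_ratio: float | None
    ct_vic: np.ndarray
    ct_fam: np.ndarray

    def __post_init__(self) -> None:
        self.ct_vic = np.asarray(self.ct_vic, dtype=float)
        self.ct_fam = np.asarray(self.ct_fam, dtype=float)
        if self.ct_vic.size == 0 or self.ct_fam.size == 0:
            raise ValueError("each channel needs at least one replicate")
        if self.material == "mixture" and self.mixture_ratio is None:
            raise ValueError("mixtures must carry mixture_ratio")
        if not (np.all(np.isfinite(self.ct_vic)) and np.all(self.ct_vic > 0)
                and np.all(np.isfinite(self.ct_fam)) and np.all(self.ct_fam > 0)):
            raise ValueError("Ct values must be finite and positive")

    @property
    def delta_ct(self) -> float:
        """Replicate-mean Ct(VIC) - Ct(FAM)."""
        return float(self.ct_vic.mean() - self.ct_fam.mean())


@dataclass
class AstqExperiment:
    """A full ASTQ run: mixture series plus per-line gDNA/cDNA plates."""

    mixtures: list[AstqPlate]
    dna: list[AstqPlate]
    cdna: list[AstqPlate]


def simulate_astq_experiment(
    true_ratio: float,
    n_lines: int,
    noise_sd_ct: float,
    seed: int | np.random.Generator = 0,
    n_replicates: int = 4,
    ct_offset: float = 26.0,
    vic_probe_shift: float = 0.4,
) -> AstqExperiment:
    """Simulate the mixture standard-curve series and heterozygous cell lines.

    Ct = ``ct_offset`` - log2(template amount) + probe shift (VIC channel)
    + Normal(0, ``noise_sd_ct``).  Genomic DNA of a heterozygote carries the
    two alleles at ratio 1; cDNA carries them at ``true_ratio``.  Total
    template amount varies per sample (it cancels in Ct differences).
    """
    if true_ratio <= 0:
        raise ConfigurationError("true_ratio must be > 0")
    if n_lines <= 0:
        raise ConfigurationError("n_lines must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _plate(sample_id: str, material: str, ratio: float,
               mixture_ratio: float | None) -> AstqPlate:
        total = 2.0 ** rng.normal(0.0, 0.3)  # arbitrary per-sample input amount
        amt_vic = total * ratio / (1.0 + ratio)
        amt_fam = total * 1.0 / (1.0 + ratio)
        ct_v = (ct_offset - np.log2(amt_vic) + vic_probe_shift
                + rng.normal(0.0, noise_sd_ct, size=n_replicates))
        ct_f = (ct_offset - np.log2(amt_fam)
                + rng.normal(0.0, noise_sd_ct, size=n_replicates))
        return AstqPlate(sample_id, material, mixture_ratio, ct_v, ct_f)

    mixtures = [
        _plate(f"mix_{i}", "mixture", r, r) for i, r in enumerate(MIXTURE_SERIES)
    ]
    dna = [_plate(f"line_{i:02d}", "genomic_dna", 1.0, None) for i in range(n_lines)]
    cdna = [_plate(f"line_{i:02d}", "cdna", true_ratio, None) for i in range(n_lines)]
    return AstqExperiment(mixtures=mixtures, dna=dna, cdna=cdna)
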