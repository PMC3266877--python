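"""SNP selection and staging: compound GWAS+eQTL thresholds, clumping,
known-locus exclusion, pooled-scan cross-referencing, and replication gates.

The selection rule implemented here is the compound discovery filter: keep a
SNP when its discovery-stage trend P is below ``p_select_strong`` (1e-4)
outright, or when it sits in the mid-P band [1e-4, 1e-3) *and* is cis-eQTL
positive.  Candidates are then clumped to the best SNP per locus, known
susceptibility loci are removed, and external pooled-scan support (LD
r^2 > 0.5 or +/-100 kb proximity to a pooled signal with rank-based
P < 0.01) gates entry into replication.  Replication proceeds through a
combined-P gate (Mantel-Haenszel over discovery + first replication,
P < 1e-6) before the final all-stage combination is held to genome-wide
significance (P < 5e-8).

Every SNP exits with exactly one terminal stage and an ordered reason
chain, so selection decisions are fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .association import AlleleTable2x2, mantel_haenszel
from .containers import MISSING, GenotypeMatrix, SlepipeError

__all__ = [
    "SelectionThresholds",
    "LdStats",
    "ld_r2_dprime",
    "haplotype_frequencies_em",
    "rank_based_p",
    "select_candidates",
    "clump_best_per_locus",
    "exclude_known_loci",
    "pooled_support",
    "replication_gates",
]


@dataclass(frozen=True)
class SelectionThresholds:
    """Thresholds of the staged selection procedure (defaults as used)."""

    p_select_strong: float = 1.0e-4
    p_select_eqtl: float = 1.0e-3
    pooled_rank_p: float = 0.01
    pooled_ld_r2: float = 0.5
    pooled_distance_bp: int = 100_000
    p_stage_gate: float = 1.0e-6
    p_genomewide: float = 5.0e-8
    locus_window_bp: int = 500_000
    exclusion_window_bp: int = 200_000

    def __post_init__(self) -> None:
        if not (0 < self.p_select_strong < self.p_select_eqtl < 1):
            raise ValueError("need 0 < p_select_strong < p_select_eqtl < 1")
        for name in ("pooled_rank_p", "p_stage_gate", "p_genomewide"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class LdStats:
    """Pairwise linkage disequilibrium from estimated haplotype frequencies."""

    snp_pair: tuple[str, str]
    r_squared: float
    d_prime: float
    n_iterations: int = 0


# ---------------------------------------------------------------------------
# LD via EM haplotype frequencies
# ---------------------------------------------------------------------------

def haplotype_frequencies_em(
    g1: np.ndarray, g2: np.ndarray,
    tol: float = 1e-10, max_iter: int = 1000,
) -> tuple[np.ndarray, int]:
    """EM haplotype frequencies (AB, Ab, aB, ab) from unphased genotypes.

    Only the double heterozygote is phase-ambiguous; EM iterates until the
    largest frequency change is below ``tol``.  Raises on non-convergence.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING) & np.isfinite(g1) & np.isfinite(g2)
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    if n == 0:
        raise SlepipeError("no complete genotype pairs for LD estimation")
    if g1.std() == 0 or g2.std() == 0:
        raise SlepipeError("LD undefined for a monomorphic SNP")
    # genotype cross-tab
    tab = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            tab[a, b] = np.sum((g1 == a) & (g2 == b))
    # known haplotype contributions (counts of AB, Ab, aB, ab per cell),
    # allele "A"/"B" = allele 1 (dosage-counted) at each SNP
    pA, pB = g1.mean() / 2, g2.mean() / 2
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    n_dh = tab[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    base = np.zeros(4)
    for a in range(3):
        for b in range(3):
            if a == 1 and b == 1:
                continue
            c = tab[a, b]
            if c == 0:
                continue
            base += c * _phase_known(a, b)
    for it in range(max_iter):
        if n_dh > 0:
            denom = f[0] * f[3] + f[1] * f[2]
            w_cis = (f[0] * f[3]) / denom if denom > 0 else 0.5
        else:
            w_cis = 0.0
        counts = base.copy()
        if n_dh > 0:
            counts += n_dh * np.array([w_cis, 1 - w_cis, 1 - w_cis, w_cis])
        new = counts / (2 * n)
        if np.max(np.abs(new - f)) < tol:
            return new, it + 1
        f = new
    raise SlepipeError(f"haplotype EM did not converge in {max_iter} iterations")


def _phase_known(a: int, b: int) -> np.ndarray:
    """Haplotype counts (AB, Ab, aB, ab) for an unambiguous genotype pair."""
    # one haplotype carries min(allele availability); enumerate directly
    combos = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    return np.array(combos[(a, b)], dtype=float)


def ld_r2_dprime(
    genotypes: GenotypeMatrix, snp_a: int | str, snp_b: int | str,
) -> LdStats:
    """r^2 and D' between two SNPs from EM haplotype frequencies."""
    ja = genotypes.snp_index(snp_a) if isinstance(snp_a, str) else int(snp_a)
    jb = genotypes.snp_index(snp_b) if isinstance(snp_b, str) else int(snp_b)
    g1 = genotypes.genotypes[:, ja]
    g2 = genotypes.genotypes[:, jb]
    f, iters = haplotype_frequencies_em(g1, g2)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    D = f[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D**2 / denom if denom > 0 else 0.0
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dp = abs(D) / dmax if dmax > 0 else 0.0
    ids = (str(genotypes.snps["snp_id"].iloc[ja]),
           str(genotypes.snps["snp_id"].iloc[jb]))
    return LdStats(snp_pair=ids, r_squared=min(r2, 1.0),
                   d_prime=min(dp, 1.0), n_iterations=iters)


# ---------------------------------------------------------------------------
# rank-based P
# ---------------------------------------------------------------------------

def rank_based_p(scores: np.ndarray) -> np.ndarray:
    """p_i = rank_i / N with rank 1 the most extreme (largest) score.

    Ties receive average ranks, so equal scores share
    ``(N + 1) / (2N)`` when all are identical.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise SlepipeError("rank_based_p on empty scores")
    if not np.all(np.isfinite(s)):
        raise SlepipeError("scores must be finite")
    ranks = rankdata(-s, method="average")
    return ranks / s.size


# ---------------------------------------------------------------------------
# selection stages
# ---------------------------------------------------------------------------

def _init_decisions(gwas_results: pd.DataFrame) -> pd.DataFrame:
    d = gwas_results[["snp_id", "chrom", "pos", "p"]].copy()
    d = d.rename(columns={"p": "p_gwas"})
    d["selected"] = False
    d["stage"] = "rejected"
    d["reasons"] = [[] for _ in range(len(d))]
    d["supporting_pooled_snp"] = None
    for col in ("p_combined12", "or_combined12", "p_combined_all", "or_mh"):
        d[col] = np.nan
    return d


def select_candidates(
    gwas_results: pd.DataFrame,
    eqtl_flags: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Apply the compound GWAS + eQTL selection rule.

    ``p < p_select_strong`` selects outright; the mid band
    ``[p_select_strong, p_select_eqtl)`` selects only eQTL-positive SNPs.
    Boundaries are strict/inclusive exactly as stated: p equal to
    ``p_select_strong`` falls into the mid band.
    """
    flags = eqtl_flags.set_index("snp_id")["positive"]
    d = _init_decisions(gwas_results)
    pos = d["snp_id"].map(flags).fillna(False).astype(bool)
    d["eqtl_positive"] = pos
    p = d["p_gwas"]
    strong = p < thresholds.p_select_strong
    midband = (p >= thresholds.p_select_strong) & (p < thresholds.p_select_eqtl)
    d.loc[strong, "selected"] = True
    d.loc[strong, "stage"] = "gwas_selected"
    for i in d.index[strong]:
        d.at[i, "reasons"] = ["gwas_strong"]
    mid_pos = midband & pos
    d.loc[mid_pos, "selected"] = True
    d.loc[mid_pos, "stage"] = "gwas_selected"
    for i in d.index[mid_pos]:
        d.at[i, "reasons"] = ["gwas_midband_eqtl_positive"]
    mid_neg = midband & ~pos
    for i in d.index[mid_neg]:
        d.at[i, "reasons"] = ["eqtl_negative_midband"]
    weak = p >= thresholds.p_select_eqtl
    for i in d.index[weak]:
        d.at[i, "reasons"] = ["gwas_weak"]
    return d


def clump_best_per_locus(
    decisions: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Keep the most significant selected SNP per locus (greedy by P).

    Greedy pass in ascending P (ties: smaller position, then id): keeping a
    SNP suppresses every other selected SNP within the locus window on the
    same chromosome.
    """
    d = decisions.copy()
    sel = d[d["selected"]].sort_values(["p_gwas", "pos", "snp_id"])
    kept: list[tuple[int, int]] = []  # (chrom, pos)
    for i, row in sel.iterrows():
        if any(c == row["chrom"]
               and abs(p - row["pos"]) <= thresholds.locus_window_bp
               for c, p in kept):
            d.at[i, "selected"] = False
            d.at[i, "stage"] = "rejected"
            d.at[i, "reasons"] = list(d.at[i, "reasons"]) + ["clumped"]
        else:
            kept.append((row["chrom"], row["pos"]))
    return d


def exclude_known_loci(
    decisions: pd.DataFrame,
    known_loci: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Reject candidates within the exclusion window of a known locus."""
    d = decisions.copy()
    if known_loci is None or known_loci.empty:
        return d
    for i, row in d[d["selected"]].iterrows():
        near = known_loci[
            (known_loci["chrom"] == row["chrom"])
            & ((known_loci["pos"] - row["pos"]).abs()
               <= thresholds.exclusion_window_bp)
        ]
        if len(near):
            d.at[i, "selected"] = False
            d.at[i, "stage"] = "rejected"
            d.at[i, "reasons"] = list(d.at[i, "reasons"]) + ["known_locus"]
    return d


def pooled_support(
    decisions: pd.DataFrame,
    pooled_table: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Cross-reference candidates against pooled-scan association signals.

    A candidate survives when some pooled SNP with rank-based P below
    ``pooled_rank_p`` lies within ``pooled_distance_bp`` of it, or is in LD
    (r^2 > ``pooled_ld_r2``) with it.  LD is only computable when both
    markers are present in ``genotypes``; otherwise the distance criterion
    alone applies and the decision is annotated.
    """
    if pooled_table is None or pooled_table.empty:
        raise SlepipeError("pooled_support requires a nonempty pooled table")
    d = decisions.copy()
    sig = pooled_table[pooled_table["rank_p"] < thresholds.pooled_rank_p]
    snp_ids = set(genotypes.snps["snp_id"]) if genotypes is not None else set()
    for i, row in d[d["selected"]].iterrows():
        support = None
        ld_unavailable = False
        near = sig[(sig["chrom"] == row["chrom"])
                   & ((sig["pos"] - row["pos"]).abs()
                      <= thresholds.pooled_distance_bp)]
        if len(near):
            support = near.sort_values("rank_p")["snp_id"].iloc[0]
        else:
            same_chrom = sig[sig["chrom"] == row["chrom"]]
            for _, prow in same_chrom.iterrows():
                if genotypes is None or prow["snp_id"] not in snp_ids \
                        or row["snp_id"] not in snp_ids:
                    ld_unavailable = True
                    continue
                try:
                    ld = ld_r2_dprime(genotypes, row["snp_id"], prow["snp_id"])
                except SlepipeError:
                    continue
                if ld.r_squared > thresholds.pooled_ld_r2:
                    support = prow["snp_id"]
                    break
        if support is not None:
            d.at[i, "stage"] = "pooled_supported"
            d.at[i, "supporting_pooled_snp"] = support
        else:
            d.at[i, "selected"] = False
            d.at[i, "stage"] = "rejected"
            reasons = list(d.at[i, "reasons"]) + ["no_pooled_support"]
            if ld_unavailable:
                reasons.append("ld_unavailable_distance_only")
            d.at[i, "reasons"] = reasons
    return d


# ---------------------------------------------------------------------------
# replication gates
# ---------------------------------------------------------------------------

_AMBIGUOUS = {frozenset("AT"), frozenset("GC")}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _check_alleles(snp_id: str, a1: str, a2: str, b1: str, b2: str) -> None:
    if (a1, a2) == (b1, b2):
        return
    if frozenset((a1, a2)) in _AMBIGUOUS:
        raise SlepipeError(
            f"ambiguous-strand SNP {snp_id}: orientation metadata required")
    flipped = (_COMPLEMENT.get(b1, "?"), _COMPLEMENT.get(b2, "?"))
    if (a1, a2) == flipped:
        return  # pure strand flip, same allele ordering
    raise SlepipeError(f"allele mismatch between stages for SNP {snp_id}")


def replication_gates(
    gwas_tables: dict[str, AlleleTable2x2],
    rep1_tables: dict[str, AlleleTable2x2],
    rep2_tables: dict[str, AlleleTable2x2],
    decisions: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
    alleles: dict[str, dict[str, tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Run the staged replication gates over pooled-supported candidates.

    For each candidate: combine discovery and first-replication tables by
    Mantel-Haenszel; P below ``p_stage_gate`` admits the SNP to the second
    replication, after which all three stages are combined and held to
    ``p_genomewide``.  A candidate missing from a required stage is an
    error, never a silent skip.
    """
    d = decisions.copy()
    for col in ("p_combined12", "or_combined12", "p_combined_all", "or_mh"):
        if col not in d.columns:
            d[col] = np.nan
    for i, row in d[d["stage"] == "pooled_supported"].iterrows():
        sid = row["snp_id"]
        if sid not in gwas_tables:
            raise SlepipeError(f"missing discovery-stage table for {sid}")
        if sid not in rep1_tables:
            raise SlepipeError(f"missing replication-1 table for {sid}")
        if alleles:
            ref = alleles.get("gwas", {}).get(sid)
            for stage_name in ("rep1", "rep2"):
                other = alleles.get(stage_name, {}).get(sid)
                if ref and other:
                    _check_alleles(sid, *ref, *other)
        meta12 = mantel_haenszel([gwas_tables[sid], rep1_tables[sid]], sid)
        d.at[i, "p_combined12"] = meta12.p_combined
        d.at[i, "or_combined12"] = meta12.or_mh
        if meta12.p_combined >= thresholds.p_stage_gate:
            d.at[i, "selected"] = False
            d.at[i, "stage"] = "rejected"
            d.at[i, "reasons"] = list(d.at[i, "reasons"]) + ["stage_gate_failed"]
            continue
        d.at[i, "stage"] = "rep1_passed"
        if sid not in rep2_tables:
            raise SlepipeError(f"missing replication-2 table for {sid}")
        meta_all = mantel_haenszel(
            [gwas_tables[sid], rep1_tables[sid], rep2_tables[sid]], sid)
        d.at[i, "p_combined_all"] = meta_all.p_combined
        d.at[i, "or_mh"] = meta_all.or_mh
        if meta_all.p_combined < thresholds.p_genomewide:
            d.at[i, "stage"] = "final_significant"
            d.at[i, "reasons"] = list(d.at[i, "reasons"]) + ["genome_wide"]
        else:
            d.at[i, "selected"] = False
            d.at[i, "stage"] = "rejected"
            d.at[i, "reasons"] = list(d.at[i, "reasons"]) + ["not_genome_wide"]
    return d


def decisions_to_tsv_frame(decisions: pd.DataFrame) -> pd.DataFrame:
    """Flatten the reasons list for TSV output."""
    out = decisions.copy()
    out["reason_codes"] = out["reasons"].map(
        lambda r: ";".join(r) if isinstance(r, (list, tuple)) else str(r))
    return out.drop(columns=["reasons"])
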