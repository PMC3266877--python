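"""End-to-end orchestration of the staged discovery pipeline on synthetic data.

``run_study`` walks a synthetic cohort through the whole design: QC, the
discovery-stage trend-test scan, cis-eQTL positivity flags, compound
selection with clumping and pooled-scan support, and the two replication
gates combined by Mantel-Haenszel.  Every stage output is returned so the
caller (CLI or test) can write a full audit report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import AlleleTable2x2, stage_association_scan
from .containers import GenotypeMatrix
from .eqtl import eqtl_scan, flag_eqtl_positive
from .prioritize import (
    SelectionThresholds,
    clump_best_per_locus,
    exclude_known_loci,
    pooled_support,
    replication_gates,
    select_candidates,
)
from .qc import QcReport, QcThresholds, lambda_gc, run_qc
from .synthetic import SimulationConfig, simulate_cohort, simulate_expression, \
    simulate_pooled_scan

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    """All stage outputs of one synthetic study run."""

    gwas: pd.DataFrame
    eqtl: pd.DataFrame
    eqtl_flags: pd.DataFrame
    pooled: pd.DataFrame
    decisions: pd.DataFrame
    lambda_gc: float
    qc_report: QcReport | None = None
    truth: pd.DataFrame | None = None


def _allele_tables(scan: pd.DataFrame, snp_ids: list[str],
                   stage: str) -> dict[str, AlleleTable2x2]:
    out = {}
    sub = scan.set_index("snp_id")
    for sid in snp_ids:
        row = sub.loc[sid]
        a = round(2 * row["n_case"] * row["freq_case"])
        b = 2 * row["n_case"] - a
        c = round(2 * row["n_control"] * row["freq_control"])
        d = 2 * row["n_control"] - c
        out[sid] = AlleleTable2x2(a, b, c, d, stage)
    return out


def run_study(
    config: SimulationConfig,
    rep1_size: tuple[int, int] = (562, 653),
    rep2_size: tuple[int, int] = (825, 27911),
    qc_thresholds: QcThresholds = QcThresholds(),
    selection: SelectionThresholds = SelectionThresholds(),
    known_loci: pd.DataFrame | None = None,
    eqtl_window_bp: int = 300_000,
    eqtl_q_threshold: float = 0.2,
    do_qc: bool = True,
) -> StudyResult:
    """Run the full staged design on one synthetic realisation.

    The discovery cohort has the sizes in ``config``; the two replication
    cohorts are drawn from the same marker panel (identical haplotype
    pools) with independent subjects at the given sizes.
    """
    cohort = simulate_cohort(config, stage="gwas")
    panel: GenotypeMatrix = cohort.genotypes
    qc_report = None
    if do_qc:
        panel, qc_report = run_qc(panel, qc_thresholds)
    gwas = stage_association_scan(panel, stage="gwas")
    lam = lambda_gc(gwas["chi2"].to_numpy())

    expr, probes = simulate_expression(cohort.genotypes, config)
    eqtl_table = eqtl_scan(cohort.genotypes, expr, probes,
                           window_bp=eqtl_window_bp)
    flags = flag_eqtl_positive(eqtl_table, gwas["snp_id"],
                               q_threshold=eqtl_q_threshold)

    pooled = simulate_pooled_scan(cohort.truth, cohort.genotypes.snps, config)

    decisions = select_candidates(gwas, flags, selection)
    decisions = clump_best_per_locus(decisions, selection)
    decisions = exclude_known_loci(decisions, known_loci, selection)
    decisions = pooled_support(decisions, pooled, cohort.genotypes, selection)

    candidates = decisions.loc[decisions["selected"], "snp_id"].tolist()
    if candidates:
        rep1 = simulate_cohort(
            replace(config, n_cases=rep1_size[0], n_controls=rep1_size[1]),
            stage="rep1", substream=1)
        rep2 = simulate_cohort(
            replace(config, n_cases=rep2_size[0], n_controls=rep2_size[1]),
            stage="rep2", substream=2)
        rep1_scan = stage_association_scan(rep1.genotypes, stage="rep1")
        rep2_scan = stage_association_scan(rep2.genotypes, stage="rep2")
        gwas_tab = _allele_tables(gwas, candidates, "gwas")
        rep1_tab = _allele_tables(rep1_scan, candidates, "rep1")
        rep2_tab = _allele_tables(rep2_scan, candidates, "rep2")
        decisions = replication_gates(gwas_tab, rep1_tab, rep2_tab,
                                      decisions, selection)

    return StudyResult(gwas=gwas, eqtl=eqtl_table, eqtl_flags=flags,
                       pooled=pooled, decisions=decisions, lambda_gc=lam,
                       qc_report=qc_report, truth=cohort.truth)
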