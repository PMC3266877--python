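"""QC: call-rate filters, HWE exact test, IBD relatedness, PCA, lambda_GC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from slepipe import (
    GenotypeCounts,
    QcThresholds,
    SimulationConfig,
    estimate_ibd,
    filter_samples_by_call_rate,
    filter_snps,
    flag_related_pairs,
    hwe_exact_test,
    lambda_gc,
    pca_ancestry_outliers,
    run_qc,
    simulate_genotypes,
)
from slepipe.containers import CASE, CONTROL, MISSING, SlepipeError

from conftest import make_matrix


# ---------------------------------------------------------------------------
# HWE exact test vs an independent enumeration oracle
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Independent brute-force: enumerate every heterozygote count with the
    same allele totals, computing probabilities by the exact recurrence."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_alt + n_het
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    hets = list(range(n_rare % 2, n_rare + 1, 2))
    # unnormalised probabilities via the ratio recurrence
    probs = {hets[0]: 1.0}
    for h in hets[1:]:
        prev = probs[h - 2]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        # P(h)/P(h-2) = 4*(hom_r+1)*(hom_c+1) / (h*(h-1))
        probs[h] = prev * 4.0 * (hom_r + 1) * (hom_c + 1) / (h * (h - 1))
    total = sum(probs.values())
    obs = n_het
    p_obs = probs[obs] / total
    return min(1.0, sum(v / total for v in probs.values()
                        if v / total <= p_obs * (1 + 1e-9)))


class TestHweExactTest:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(GenotypeCounts(0, 0, 50)) == 1.0
        assert hwe_exact_test(GenotypeCounts(50, 0, 0)) == 1.0

    def test_matches_enumeration_oracle_spot(self):
        p = hwe_exact_test(GenotypeCounts(25, 50, 25))
        assert p == pytest.approx(hwe_enumeration_oracle(25, 50, 25), abs=1e-12)

    def test_extreme_heterozygosity_flaggable(self):
        assert hwe_exact_test(GenotypeCounts(0, 100, 0)) < 1e-6
        assert hwe_exact_test(GenotypeCounts(200, 0, 200)) < 1e-6

    def test_all_missing_rejected(self):
        with pytest.raises(SlepipeError):
            hwe_exact_test(GenotypeCounts(0, 0, 0, n_missing=10))

    def test_equals_oracle_on_random_tables(self):
        """Agreement with the enumeration oracle on random genotype tables
        (the exhaustive small-table sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(12)
        for _ in range(500):
            n = int(rng.integers(1, 400))
            n_a = int(rng.integers(0, n + 1))
            het = int(rng.choice(np.arange(n_a % 2, n_a + 1, 2))) if n_a else 0
            hom_alt = (n_a - het) // 2
            hom_ref = n - het - hom_alt
            if hom_ref < 0:
                continue
            mine = hwe_exact_test(GenotypeCounts(hom_ref, het, hom_alt))
            oracle = hwe_enumeration_oracle(hom_ref, het, hom_alt)
            assert mine == pytest.approx(oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestSampleFilter:
    def test_complete_sample_retained(self):
        gm = make_matrix(np.zeros((4, 100)))
        rep = filter_samples_by_call_rate(gm)
        assert rep.excluded_samples.empty

    def test_boundary_call_rate_retained(self):
        g = np.zeros((3, 100), dtype=np.int8)
        g[0, :2] = MISSING   # exactly 0.98
        g[1, :3] = MISSING   # 0.97 -> excluded
        gm = make_matrix(g)
        rep = filter_samples_by_call_rate(gm)
        assert rep.excluded_samples["sample_id"].tolist() == ["i1"]

    def test_corruption_fixture_bookkeeping(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(50, 200)).astype(np.int8)
        bad = [3, 17, 42]
        for i in bad:
            g[i, rng.random(200) < 0.1] = MISSING
        gm = make_matrix(g)
        rep = filter_samples_by_call_rate(gm)
        assert set(rep.excluded_samples["sample_id"]) == {f"i{i}" for i in bad}


class TestSnpFilter:
    def _labelled(self, g):
        n = g.shape[0]
        status = [CASE] * (n // 2) + [CONTROL] * (n - n // 2)
        return make_matrix(g, status=status)

    def test_monomorphic_flagged_maf(self):
        g = np.ones((40, 3), dtype=np.int8)
        g[:, 0] = 0  # monomorphic
        g[::2, 1] = 0
        g[::2, 2] = 0
        gm = self._labelled(g)
        rep = filter_snps(gm)
        row = rep.excluded_snps.set_index("snp_id").loc["s0"]
        assert row["reason"] == "maf"

    def test_hwe_violation_flagged(self):
        # controls: 200 het-free with both homozygotes -> extreme HWE failure
        n_ctrl, n_case = 400, 400
        ctrl = np.array([0] * 200 + [2] * 200, dtype=np.int8)
        case = np.tile([0, 1, 1, 2], 100).astype(np.int8)
        g = np.column_stack([np.concatenate([case, ctrl])])
        gm = make_matrix(g, status=[CASE] * n_case + [CONTROL] * n_ctrl)
        assert hwe_exact_test(GenotypeCounts(200, 0, 200)) < 1e-6
        rep = filter_snps(gm)
        assert rep.excluded_snps.set_index("snp_id").loc["s0", "reason"] == "hwe"

    def test_perfect_hwe_not_flagged(self):
        ctrl = np.array([0] * 100 + [1] * 200 + [2] * 100, dtype=np.int8)
        case = ctrl.copy()
        g = np.column_stack([np.concatenate([case, ctrl])])
        gm = make_matrix(g, status=[CASE] * 400 + [CONTROL] * 400)
        rep = filter_snps(gm)
        assert rep.excluded_snps.empty

    def test_non_autosomal_flagged(self):
        g = np.tile([0, 1, 1, 2], 100).astype(np.int8).reshape(-1, 1)
        gm = make_matrix(g, status=[CASE] * 200 + [CONTROL] * 200,
                         chrom=[23])
        rep = filter_snps(gm)
        assert rep.excluded_snps.iloc[0]["reason"] == "non_autosomal"

    def test_qc_idempotent(self, null_cohort):
        retained, report1 = run_qc(null_cohort.genotypes)
        retained2, report2 = run_qc(retained)
        assert report2.excluded_samples.empty
        assert report2.excluded_snps.empty
        # exclusion counts partition the input
        assert (retained.n_snps + len(report1.excluded_snps)
                == null_cohort.genotypes.n_snps)


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def _unrelated_panel(n, m, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, size=m)
    g = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return make_matrix(g)


class TestIbd:
    def test_duplicate_sample_pi_hat_near_one(self):
        gm = _unrelated_panel(10, 2000, 1)
        gm.genotypes[1] = gm.genotypes[0]
        est = estimate_ibd(gm, (0, 1))
        assert est.pi_hat >= 0.95

    def test_unrelated_pi_hat_near_zero(self):
        gm = _unrelated_panel(10, 5000, 2)
        est = estimate_ibd(gm, (0, 1))
        assert est.pi_hat <= 0.1

    def test_parent_offspring_half_sharing(self):
        rng = np.random.default_rng(3)
        m = 5000
        p = rng.uniform(0.2, 0.5, size=m)
        # explicit haplotypes; child inherits one parental haplotype
        pa = (rng.random((2, m)) < p).astype(np.int8)
        other = (rng.random(m) < p).astype(np.int8)
        transmitted = np.where(rng.random(m) < 0.5, pa[0], pa[1])
        parent = pa[0] + pa[1]
        child = transmitted + other
        filler = rng.binomial(2, p, size=(8, m)).astype(np.int8)
        gm = make_matrix(np.vstack([parent, child, filler]))
        est = estimate_ibd(gm, (0, 1))
        assert 0.4 <= est.pi_hat <= 0.6

    def test_low_information_flagged(self):
        gm = _unrelated_panel(4, 50, 4)
        assert estimate_ibd(gm, (0, 1)).low_information


class TestRelatedPairRemoval:
    def _est(self, a, b, pihat):
        from slepipe.qc import IbdEstimate
        return IbdEstimate((a, b), 0.0, 0.0, 0.0, pihat, 1000)

    def test_no_pairs_above_threshold(self):
        gm = _unrelated_panel(4, 100, 5)
        out = flag_related_pairs([self._est("i0", "i1", 0.05)], gm)
        assert out.empty

    def test_single_duplicate_removes_one(self):
        gm = _unrelated_panel(4, 100, 6)
        out = flag_related_pairs([self._est("i0", "i1", 0.99)], gm)
        assert len(out) == 1

    def test_chain_removal_leaves_no_flagged_pair(self):
        gm = _unrelated_panel(5, 100, 7)
        ests = [self._est("i0", "i1", 0.9), self._est("i1", "i2", 0.8)]
        out = flag_related_pairs(ests, gm)
        dropped = set(out["sample_id"])
        # brute-force residual check: every flagged pair broken
        for e in ests:
            assert e.sample_pair[0] in dropped or e.sample_pair[1] in dropped
        assert len(dropped) <= 2


# ---------------------------------------------------------------------------
# PCA ancestry
# ---------------------------------------------------------------------------

class TestPca:
    def test_homogeneous_cohort_no_outliers(self):
        cfg = SimulationConfig(n_cases=60, n_controls=60, n_snps=300,
                               n_blocks=60, seed=8, missing_rate=0.0)
        gm = simulate_genotypes(cfg, n_samples=120)
        coords, outliers, warns = pca_ancestry_outliers(gm, None)
        assert not outliers.any()
        assert warns  # no reference panel -> warning

    def test_divergent_sample_flagged(self):
        rng = np.random.default_rng(9)
        m = 400
        p = rng.uniform(0.2, 0.5, size=m)
        g = rng.binomial(2, p, size=(80, m)).astype(np.int8)
        # divergent ancestry: allele frequencies strongly perturbed
        p_out = np.clip(p + rng.choice([-0.4, 0.4], size=m), 0.02, 0.98)
        g[0] = rng.binomial(2, p_out)
        gm = make_matrix(g)
        coords, outliers, _ = pca_ancestry_outliers(
            gm, None, QcThresholds(pca_outlier_sd=6.0), prune=False)
        assert outliers[0]
        assert outliers.sum() == 1


# ---------------------------------------------------------------------------
# genomic control
# ---------------------------------------------------------------------------

class TestLambdaGc:
    def test_null_median_gives_unity(self):
        med = chi2.ppf(0.5, 1)
        assert lambda_gc([med]) == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self):
        x = np.random.default_rng(0).chisquare(1, size=1001)
        assert lambda_gc(2 * x) == pytest.approx(2 * lambda_gc(x), rel=1e-12)

    def test_null_simulation_near_one(self):
        x = np.random.default_rng(1).chisquare(1, size=10000)
        assert 0.95 <= lambda_gc(x) <= 1.05

    def test_empty_rejected(self):
        with pytest.raises(SlepipeError):
            lambda_gc([])
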