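"""LD estimation, selection rules, clumping, pooled support, staged gates."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from slepipe import (
    AlleleTable2x2,
    SelectionThresholds,
    SimulationConfig,
    clump_best_per_locus,
    exclude_known_loci,
    haplotype_frequencies_em,
    ld_r2_dprime,
    pooled_support,
    rank_based_p,
    replication_gates,
    select_candidates,
    simulate_genotypes,
)
from slepipe.containers import SlepipeError

from conftest import make_matrix


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

class TestLd:
    def test_identical_columns_perfect_ld(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.4, size=500).astype(np.int8)
        gm = make_matrix(np.column_stack([col, col]))
        ld = ld_r2_dprime(gm, 0, 1)
        assert ld.r_squared == pytest.approx(1.0, abs=1e-9)
        assert ld.d_prime == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_low_r2(self):
        rng = np.random.default_rng(1)
        g = np.column_stack([rng.binomial(2, 0.3, 2000),
                             rng.binomial(2, 0.4, 2000)]).astype(np.int8)
        ld = ld_r2_dprime(make_matrix(g), 0, 1)
        assert ld.r_squared < 0.05

    def test_em_matches_phased_haplotype_counts(self):
        """On simulated phased data the EM frequencies agree with direct
        haplotype counting to 1e-8 (well-separated optimum)."""
        cfg = SimulationConfig(n_cases=1000, n_controls=1000, n_snps=10,
                               n_blocks=1, block_ld_rho=0.7, seed=2,
                               missing_rate=0.0)
        gm, (h1, h2) = simulate_genotypes(cfg, return_haplotypes=True)
        for j in range(0, 9, 2):
            ha = np.concatenate([h1[:, j], h2[:, j]])
            hb = np.concatenate([h1[:, j + 1], h2[:, j + 1]])
            counted = np.array([
                np.mean((ha == 1) & (hb == 1)),
                np.mean((ha == 1) & (hb == 0)),
                np.mean((ha == 0) & (hb == 1)),
                np.mean((ha == 0) & (hb == 0))])
            f, _ = haplotype_frequencies_em(gm.genotypes[:, j],
                                            gm.genotypes[:, j + 1])
            # EM sees only the genotype cross-tab; the double-het split is
            # random in truth, so compare at the EM's own resolution
            np.testing.assert_allclose(f, counted, atol=2e-2)
            # marginals must match exactly
            assert f[0] + f[1] == pytest.approx(ha.mean(), abs=1e-8)
            assert f[0] + f[2] == pytest.approx(hb.mean(), abs=1e-8)

    def test_em_exact_on_phase_unambiguous_fixture(self):
        """Without double heterozygotes the haplotype counts are fully
        determined; EM must reproduce them to 1e-8."""
        # genotypes chosen so no (1,1) cell occurs
        g1 = np.array([0, 0, 2, 2, 1, 1, 0, 2, 1, 0] * 30, dtype=np.int8)
        g2 = np.array([0, 1, 2, 1, 0, 2, 2, 0, 0, 1] * 30, dtype=np.int8)
        f, _ = haplotype_frequencies_em(g1, g2)
        # direct count: phase-known decomposition of each genotype pair
        from slepipe.prioritize import _phase_known
        total = np.zeros(4)
        for a, b in zip(g1, g2):
            total += _phase_known(int(a), int(b))
        np.testing.assert_allclose(f, total / total.sum(), atol=1e-8)

    def test_monomorphic_rejected(self):
        gm = make_matrix(np.column_stack([np.ones(50), np.zeros(50)]))
        with pytest.raises(SlepipeError):
            ld_r2_dprime(gm, 0, 1)


# ---------------------------------------------------------------------------
# rank-based P
# ---------------------------------------------------------------------------

class TestRankBasedP:
    def test_most_extreme_gets_smallest_p(self):
        scores = np.arange(100).astype(float)
        p = rank_based_p(scores)
        assert p[np.argmax(scores)] == pytest.approx(0.01)

    def test_all_ties_share_average(self):
        p = rank_based_p(np.ones(10))
        np.testing.assert_allclose(p, (10 + 1) / (2 * 10))

    def test_uniform_under_random_scores(self):
        p = rank_based_p(np.random.default_rng(3).normal(size=10000))
        assert kstest(p, "uniform").pvalue > 0.01

    def test_empty_rejected(self):
        with pytest.raises(SlepipeError):
            rank_based_p(np.array([]))


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def gwas_frame(ps, chrom=None, pos=None):
    n = len(ps)
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "chrom": chrom if chrom is not None else [1] * n,
        "pos": pos if pos is not None else [10_000_000 * (i + 1) for i in range(n)],
        "p": ps})


def flags_frame(ids, positives):
    return pd.DataFrame({"snp_id": ids, "positive": positives})


class TestSelectCandidates:
    def test_compound_rule_boundaries(self):
        ps = [5e-5, 5e-4, 5e-4, 1e-4, 5e-3]
        pos = [False, True, False, False, True]
        d = select_candidates(gwas_frame(ps),
                              flags_frame([f"s{i}" for i in range(5)], pos))
        assert d["selected"].tolist() == [True, True, False, False, False]
        assert d.loc[2, "reasons"] == ["eqtl_negative_midband"]
        # exactly p = 1e-4 with negative flag: mid band requires positivity
        assert d.loc[3, "reasons"] == ["eqtl_negative_midband"]
        assert d.loc[4, "reasons"] == ["gwas_weak"]

    def test_boundary_positive_midband_selected(self):
        d = select_candidates(gwas_frame([1e-4]), flags_frame(["s0"], [True]))
        assert d["selected"].iloc[0]


class TestClump:
    def test_nearby_pair_keeps_smaller_p(self):
        d = select_candidates(
            gwas_frame([1e-6, 1e-5], pos=[1_000_000, 1_010_000]),
            flags_frame(["s0", "s1"], [False, False]))
        out = clump_best_per_locus(d)
        assert out["selected"].tolist() == [True, False]
        assert "clumped" in out.loc[1, "reasons"]

    def test_tie_breaks_on_position(self):
        d = select_candidates(
            gwas_frame([1e-6, 1e-6], pos=[1_200_000, 1_000_000]),
            flags_frame(["s0", "s1"], [False, False]))
        out = clump_best_per_locus(d)
        assert out.loc[1, "selected"]
        assert not out.loc[0, "selected"]

    def test_matches_greedy_interval_oracle(self):
        rng = np.random.default_rng(4)
        n = 60
        ps = rng.uniform(1e-8, 5e-5, n)
        pos = np.sort(rng.integers(1, 20_000_000, n))
        chrom = rng.integers(1, 3, n)
        d = select_candidates(gwas_frame(ps, chrom=chrom, pos=pos),
                              flags_frame([f"s{i}" for i in range(n)],
                                          [False] * n))
        out = clump_best_per_locus(d, SelectionThresholds())
        # independent greedy oracle
        order = sorted(range(n), key=lambda i: (ps[i], pos[i], f"s{i}"))
        kept = []
        for i in order:
            if all(chrom[i] != chrom[j] or abs(int(pos[i]) - int(pos[j])) > 500_000
                   for j in kept):
                kept.append(i)
        expected = {f"s{i}" for i in kept}
        assert set(out.loc[out["selected"], "snp_id"]) == expected


class TestKnownLoci:
    def test_candidate_near_known_locus_rejected(self):
        d = select_candidates(gwas_frame([1e-6], pos=[1_050_000]),
                              flags_frame(["s0"], [False]))
        known = pd.DataFrame({"chrom": [1], "pos": [1_000_000]})
        out = exclude_known_loci(d, known)
        assert not out["selected"].iloc[0]
        assert "known_locus" in out.loc[0, "reasons"]

    def test_empty_known_list_no_change(self):
        d = select_candidates(gwas_frame([1e-6]), flags_frame(["s0"], [False]))
        out = exclude_known_loci(d, pd.DataFrame(columns=["chrom", "pos"]))
        assert out["selected"].iloc[0]


class TestPooledSupport:
    def _decisions(self, pos=5_000_000):
        return select_candidates(gwas_frame([1e-6], pos=[pos]),
                                 flags_frame(["s0"], [False]))

    def pooled(self, pos, rank_p):
        return pd.DataFrame({"snp_id": ["pool_x"], "chrom": [1],
                             "pos": [pos], "rank_p": [rank_p]})

    def test_boundary_distance_supported(self):
        d = pooled_support(self._decisions(), self.pooled(5_099_999, 0.005))
        assert d["stage"].iloc[0] == "pooled_supported"
        assert d["supporting_pooled_snp"].iloc[0] == "pool_x"

    def test_weak_pooled_signal_not_supporting(self):
        d = pooled_support(self._decisions(), self.pooled(5_001_000, 0.02))
        assert not d["selected"].iloc[0]
        assert "no_pooled_support" in d.loc[0, "reasons"]

    def test_ld_support_via_genotypes(self):
        rng = np.random.default_rng(5)
        col = rng.binomial(2, 0.4, 500).astype(np.int8)
        gm = make_matrix(np.column_stack([col, col]),
                         pos=[5_000_000, 9_000_000])
        d = select_candidates(gwas_frame([1e-6], pos=[5_000_000]),
                              flags_frame(["s0"], [False]))
        pooled = pd.DataFrame({"snp_id": ["s1"], "chrom": [1],
                               "pos": [9_000_000], "rank_p": [0.001]})
        out = pooled_support(d, pooled, gm)
        assert out["stage"].iloc[0] == "pooled_supported"
        assert out["supporting_pooled_snp"].iloc[0] == "s1"


class TestReplicationGates:
    def _tables(self, or_factor=2.0):
        strong = AlleleTable2x2(int(300 * or_factor), 700, 300, 700)
        return {"s0": strong}

    def _decisions(self):
        d = select_candidates(gwas_frame([1e-6]), flags_frame(["s0"], [False]))
        d = pooled_support(d, pd.DataFrame(
            {"snp_id": ["px"], "chrom": [1], "pos": [10_000_000],
             "rank_p": [0.001]}))
        assert d["stage"].iloc[0] == "pooled_supported"
        return d

    def test_missing_rep1_is_an_error(self):
        with pytest.raises(SlepipeError):
            replication_gates(self._tables(), {}, self._tables(),
                              self._decisions())

    def test_strong_signal_reaches_final(self):
        d = replication_gates(self._tables(), self._tables(), self._tables(),
                              self._decisions())
        assert d["stage"].iloc[0] == "final_significant"
        assert d["p_combined_all"].iloc[0] < 5e-8

    def test_weak_signal_fails_stage_gate_without_touching_rep2(self):
        weak = {"s0": AlleleTable2x2(310, 690, 300, 700)}
        d = replication_gates(weak, weak, {}, self._decisions())
        assert d["stage"].iloc[0] == "rejected"
        assert "stage_gate_failed" in d.loc[d.index[0], "reasons"]

    def test_null_type_one_rate_at_genomewide_threshold(self):
        """A null SNP essentially never reaches 5e-8 over many simulated
        replication series."""
        rng = np.random.default_rng(6)
        hits = 0
        n_sim = 3000
        for _ in range(n_sim):
            tables = []
            for n_case, n_ctrl in ((891, 3384), (562, 653), (825, 2000)):
                fa = 0.4
                a = rng.binomial(2 * n_case, fa)
                c = rng.binomial(2 * n_ctrl, fa)
                tables.append(AlleleTable2x2(a, 2 * n_case - a,
                                             c, 2 * n_ctrl - c))
            from slepipe import mantel_haenszel
            m = mantel_haenszel(tables)
            if m.p_combined < 5e-8:
                hits += 1
        assert hits == 0

    def test_allele_mismatch_detected(self):
        from slepipe.prioritize import _check_alleles
        _check_alleles("x", "A", "G", "A", "G")
        _check_alleles("x", "A", "G", "T", "C")  # strand flip tolerated
        with pytest.raises(SlepipeError):
            _check_alleles("x", "A", "G", "G", "A")
        with pytest.raises(SlepipeError):
            _check_alleles("x", "A", "T", "T", "A")  # ambiguous


class TestAuditCompleteness:
    def test_every_snp_has_terminal_stage_and_reasons(self, risk_cohort):
        from slepipe import run_study
        cfg, _ = risk_cohort
        res = run_study(cfg)
        d = res.decisions
        assert set(d["stage"]).issubset(
            {"rejected", "gwas_selected", "pooled_supported",
             "rep1_passed", "final_significant"})
        rejected = d[d["stage"] == "rejected"]
        assert rejected["reasons"].map(len).min() >= 1
        assert len(d) == len(res.gwas)
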