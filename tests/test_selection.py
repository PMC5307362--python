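"""Instrument-selection pipeline and instrument-strength statistics."""

import itertools
import math

import numpy as np
import pytest

from summr import (
    LDMatrix,
    SelectionConfig,
    build_candidate_panel,
    exclude_pleiotropic,
    f_statistic,
    filter_significance,
    ld_prune,
    select_instruments,
    snp_r2,
)
from summr.exceptions import ConfigError
from summr.selection import CandidateSNP

from conftest import make_record


def cand(snp, pval, flag=False, **kw):
    return CandidateSNP.from_record(make_record(snp=snp, pval=pval, **kw),
                                    pleiotropy_flag=flag)


class TestSignificanceFilter:
    def test_strict_threshold_boundary(self):
        cands = [cand("rs1", 1e-9), cand("rs2", 5e-8), cand("rs3", 1e-5)]
        retained, rejected = filter_significance(cands, 5e-8)
        assert [c.snp_id for c in retained] == ["rs1"]
        assert {c.snp_id for c in rejected} == {"rs2", "rs3"}

    def test_all_significant(self):
        cands = [cand(f"rs{i}", 1e-10) for i in range(5)]
        retained, rejected = filter_significance(cands)
        assert len(retained) == 5 and rejected == []

    def test_missing_pval_never_passes(self):
        retained, rejected = filter_significance([cand("rs1", None)])
        assert retained == [] and len(rejected) == 1

    def test_threshold_domain(self):
        with pytest.raises(ConfigError):
            filter_significance([], p_threshold=0.0)


def _brute_force_prune(cands, ld, r2):
    """Independent oracle for the pruning rule.

    The rule keeps the p-priority-lexicographically first *maximal* subset
    with all pairwise squared correlations below the threshold: enumerate
    every subset satisfying the constraint, discard non-maximal ones, rank
    members by (p, rsID) priority and take the lexicographic minimum.
    """
    prio = sorted(range(len(cands)),
                  key=lambda i: (cands[i].pval if cands[i].pval is not None else math.inf,
                                 cands[i].snp_id))
    rank = {i: r for r, i in enumerate(prio)}

    def ok(subset):
        return all(ld.pair_r(cands[i].snp_id, cands[j].snp_id) ** 2 < r2
                   for i, j in itertools.combinations(subset, 2))

    feasible = [frozenset(s) for k in range(len(cands) + 1)
                for s in itertools.combinations(range(len(cands)), k) if ok(s)]
    maximal = [s for s in feasible
               if not any(s < t for t in feasible)]
    best = min(maximal, key=lambda s: sorted(rank[i] for i in s))
    return {cands[i].snp_id for i in best}


class TestLDPrune:
    def test_high_ld_pair_keeps_smaller_p(self):
        cands = [cand("rs1", 1e-10), cand("rs2", 1e-9)]
        ld = LDMatrix(["rs1", "rs2"], [[1, 0.95], [0.95, 1]])
        retained, pruned = ld_prune(cands, ld, 0.8)
        assert [c.snp_id for c in retained] == ["rs1"]
        assert [c.snp_id for c in pruned] == ["rs2"]

    def test_identity_prunes_nothing(self):
        cands = [cand(f"rs{i}", 10.0 ** -(9 + i)) for i in range(4)]
        ld = LDMatrix.identity([c.snp_id for c in cands])
        retained, pruned = ld_prune(cands, ld)
        assert retained == cands and pruned == []

    def test_mutually_correlated_triple_keeps_single_smallest_p(self):
        cands = [cand("rsA", 1e-9), cand("rsB", 1e-12), cand("rsC", 1e-10)]
        r = np.full((3, 3), 0.92)
        np.fill_diagonal(r, 1.0)
        ld = LDMatrix(["rsA", "rsB", "rsC"], r)
        retained, _ = ld_prune(cands, ld, 0.8)
        assert [c.snp_id for c in retained] == ["rsB"]
        assert {c.snp_id for c in retained} == _brute_force_prune(cands, ld, 0.8)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(7)
        cands = [cand(f"rs{i}", float(p)) for i, p in
                 enumerate(rng.uniform(1e-12, 1e-8, size=6))]
        ids = [c.snp_id for c in cands]
        a = rng.uniform(-1, 1, size=(6, 6))
        r = np.clip((a + a.T) / 2, -0.99, 0.99)
        np.fill_diagonal(r, 1.0)
        ld = LDMatrix(ids, r)
        base = {c.snp_id for c in ld_prune(cands, ld, 0.5)[0]}
        for perm_seed in range(5):
            perm = list(np.random.default_rng(perm_seed).permutation(len(cands)))
            shuffled = [cands[i] for i in perm]
            assert {c.snp_id for c in ld_prune(shuffled, ld, 0.5)[0]} == base

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_greedy_matches_exhaustive_oracle(self, k):
        for trial in range(25):
            rng = np.random.default_rng(1000 * k + trial)
            cands = [cand(f"rs{i:02d}", float(p)) for i, p in
                     enumerate(rng.uniform(1e-12, 1e-8, size=k))]
            a = rng.uniform(-1, 1, size=(k, k))
            r = np.clip((a + a.T) / 2, -0.999, 0.999)
            np.fill_diagonal(r, 1.0)
            ld = LDMatrix([c.snp_id for c in cands], r)
            r2 = rng.choice([0.2, 0.5, 0.8])
            retained, _ = ld_prune(cands, ld, float(r2))
            assert {c.snp_id for c in retained} == _brute_force_prune(cands, ld, float(r2))

    def test_missing_snp_in_ld_is_config_error(self):
        with pytest.raises(ConfigError, match="absent"):
            ld_prune([cand("rs1", 1e-9)], LDMatrix.identity(["rsX"]))


class TestPleiotropyExclusion:
    def test_flagged_removed(self):
        cands = [cand(f"rs{i}", 1e-9, flag=(i < 2)) for i in range(13)]
        retained, excluded = exclude_pleiotropic(cands)
        assert len(retained) == 11 and len(excluded) == 2

    def test_none_flagged_identity(self):
        cands = [cand(f"rs{i}", 1e-9) for i in range(3)]
        assert exclude_pleiotropic(cands) == (cands, [])

    def test_all_flagged_empty(self):
        cands = [cand(f"rs{i}", 1e-9, flag=True) for i in range(3)]
        retained, excluded = exclude_pleiotropic(cands)
        assert retained == [] and len(excluded) == 3


class TestSelectInstruments:
    def test_packaged_panel_reproduces_accounting(self):
        cands, ld, _ = build_candidate_panel(seed=0)
        report = select_instruments(cands, ld, SelectionConfig())
        assert report.n_input == 128
        assert report.n_failed_significance == 84
        assert report.n_pruned_high_ld == 29
        assert report.n_excluded_pleiotropy == 2
        assert len(report.retained_ids) == 13

    def test_packaged_panel_independent_subset_is_four_main_snps(self):
        cands, ld, _ = build_candidate_panel(seed=0)
        report = select_instruments(cands, ld,
                                    SelectionConfig(independence_r2=0.05))
        assert sorted(report.independent_subset_ids) == sorted(
            ["rs7336933", "rs17711722", "rs17251221", "rs10491003"]
        )

    def test_empty_candidates(self):
        report = select_instruments([], LDMatrix.identity([]), SelectionConfig())
        assert report.n_input == 0 and report.retained_ids == []

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_identity_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 12))
        cands = [cand(f"rs{i:02d}", float(10 ** rng.uniform(-12, -4)),
                      flag=bool(rng.random() < 0.2)) for i in range(k)]
        a = rng.uniform(-1, 1, size=(k, k))
        r = np.clip((a + a.T) / 2, -0.99, 0.99)
        np.fill_diagonal(r, 1.0)
        report = select_instruments(cands, LDMatrix([c.snp_id for c in cands], r))
        # the SelectionReport constructor enforces the identity; recheck here
        assert (report.n_failed_significance + report.n_pruned_high_ld
                + report.n_excluded_pleiotropy + len(report.retained_ids)
                ) == report.n_input
        assert set(report.independent_subset_ids) <= set(report.retained_ids)


class TestFStatistic:
    def test_direct_evaluation_main_instrument(self):
        s = f_statistic(0.01, 4, 20611)
        assert s.F == pytest.approx(0.01 * 20606 / (0.99 * 4))
        assert round(s.F) == 52

    def test_zero_r2(self):
        assert f_statistic(0.0, 3, 100).F == 0.0

    def test_larger_r2(self):
        assert f_statistic(0.10, 4, 20611).F == pytest.approx(0.10 * 20606 / (0.90 * 4))

    def test_monotonicities(self):
        base = f_statistic(0.01, 4, 20611).F
        assert f_statistic(0.02, 4, 20611).F > base
        assert f_statistic(0.01, 4, 30000).F > base
        assert f_statistic(0.01, 5, 20611).F < base

    @pytest.mark.parametrize("r2,K,n", [(-0.1, 4, 100), (1.0, 4, 100),
                                        (0.1, 0, 100), (0.1, 4, 5)])
    def test_domain_errors(self, r2, K, n):
        with pytest.raises(ConfigError):
            f_statistic(r2, K, n)

    def test_per_snp_r2_helper(self):
        # one SNP explaining all genetic variance of a unit-variance exposure
        assert snp_r2(0.5, 1.0, 1.0) == pytest.approx(0.5)
        with pytest.raises(ConfigError):
            snp_r2(0.6, 1.0, 1.0)
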