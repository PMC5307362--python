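"""Wald ratios and the four combination estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from summr import (
    CorrelatedGLSEstimator,
    EggerRegression,
    IVWEstimator,
    WeightedMedianEstimator,
    egger,
    gls_correlated,
    ivw,
    wald_ratio,
    weighted_median,
)
from summr.exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    NumericalError,
    UndefinedRatioError,
)

from conftest import make_hset

finite_effects = st.lists(
    st.floats(0.005, 0.2), min_size=2, max_size=8
)


class TestWaldRatio:
    def test_basic_arithmetic(self):
        r = wald_ratio(0.05, 0.01, 0.02, 0.01)
        assert r.theta == pytest.approx(0.4)
        assert r.se_theta == pytest.approx(0.2)
        assert r.weight == pytest.approx(0.2 ** -2)

    def test_null_outcome(self):
        r = wald_ratio(0.05, 0.01, 0.0, 0.01)
        assert r.theta == 0.0
        assert r.se_theta == pytest.approx(0.2)

    def test_calcium_snp_example(self):
        # rs17251221-scale exposure effect with a half-sized outcome effect
        r = wald_ratio(0.061, 0.0063, 0.0305, 0.0061)
        assert r.theta == pytest.approx(0.5)
        assert r.se_theta == pytest.approx(0.1)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.02, 0.01)

    def test_second_order_se_exceeds_first_order(self):
        first = wald_ratio(0.05, 0.02, 0.02, 0.01).se_theta
        second = wald_ratio(0.05, 0.02, 0.02, 0.01, second_order=True).se_theta
        assert second > first
        assert second == pytest.approx(
            np.sqrt(0.01 ** 2 / 0.05 ** 2 + 0.02 ** 2 * 0.02 ** 2 / 0.05 ** 4)
        )


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        est = IVWEstimator().fit([0.05], [0.02], se_y=[0.01])
        assert est.beta_ == pytest.approx(0.4)
        assert est.se_ == pytest.approx(0.2)

    def test_three_snp_hand_evaluation(self):
        est = IVWEstimator().fit([0.02, 0.03, 0.06], [0.01, 0.012, 0.03],
                                 se_y=[0.01, 0.01, 0.02])
        assert est.beta_ == pytest.approx(10.1 / 22)
        assert est.se_ == pytest.approx(22 ** -0.5)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(bx=finite_effects, c=st.floats(-3, 3, allow_nan=False))
    def test_exact_proportionality(self, bx, c):
        bx = np.array(bx)
        est = IVWEstimator().fit(bx, c * bx, se_y=np.full(bx.size, 0.01))
        assert est.beta_ == pytest.approx(c, abs=1e-12)

    def test_degenerate_all_zero_exposure(self):
        with pytest.raises(DegenerateInstrumentError):
            IVWEstimator().fit([0.0, 0.0], [0.01, 0.02], se_y=[0.01, 0.01])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(scale=st.floats(0.1, 10))
    def test_scale_equivariance_in_outcome_units(self, scale):
        bx = np.array([0.02, 0.05, 0.07])
        by = np.array([0.01, -0.02, 0.03])
        sy = np.array([0.01, 0.02, 0.015])
        a = IVWEstimator().fit(bx, by, se_y=sy)
        b = IVWEstimator().fit(bx, scale * by, se_y=scale * sy)
        assert b.beta_ == pytest.approx(scale * a.beta_)
        assert b.se_ == pytest.approx(scale * a.se_)

    def test_predict_through_origin(self):
        est = IVWEstimator().fit([0.02, 0.04], [0.01, 0.02], se_y=[0.01, 0.01])
        np.testing.assert_allclose(est.predict([0.1]), [0.1 * est.beta_])


class TestCorrelatedGLS:
    def test_identity_ld_equals_ivw_to_machine_precision(self):
        rng = np.random.default_rng(11)
        for k in (1, 2, 5, 13):
            bx = rng.uniform(0.01, 0.08, k)
            by = rng.normal(0, 0.02, k)
            sy = rng.uniform(0.005, 0.03, k)
            a = IVWEstimator().fit(bx, by, se_y=sy)
            g = CorrelatedGLSEstimator().fit(bx, by, se_y=sy, ld=np.eye(k))
            assert g.beta_ == pytest.approx(a.beta_, rel=1e-14)
            assert g.se_ == pytest.approx(a.se_, rel=1e-14)

    def test_two_snp_hand_inversion(self):
        est = CorrelatedGLSEstimator().fit(
            [0.05, 0.05], [0.02, 0.03], se_y=[0.01, 0.01],
            ld=[[1, 0.5], [0.5, 1]],
        )
        assert est.beta_ == pytest.approx(0.5)
        # bX' Omega^-1 bX = 0.0025 * 1e4 / 0.75 = 100 / 3
        assert est.se_ == pytest.approx(np.sqrt(3.0 / 100.0))

    def test_single_snp_equals_wald(self):
        est = CorrelatedGLSEstimator().fit([0.05], [0.02], se_y=[0.01], ld=[[1.0]])
        assert est.beta_ == pytest.approx(0.4)

    def test_perfect_correlation_rejected_with_pruning_advice(self):
        with pytest.raises(NumericalError, match="prune"):
            CorrelatedGLSEstimator().fit([0.02, 0.03], [0.01, 0.01],
                                         se_y=[0.01, 0.01],
                                         ld=[[1, 1.0], [1.0, 1]])

    def test_non_positive_definite_names_eigenvalue(self):
        ld = [[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]]
        with pytest.raises(NumericalError, match="eigenvalue"):
            CorrelatedGLSEstimator().fit([0.02, 0.03, 0.04], [0.01] * 3,
                                         se_y=[0.01] * 3, ld=ld)


class TestWeightedMedian:
    def test_equal_weights_symmetric_median(self):
        est = WeightedMedianEstimator(n_boot=50, seed=0).fit(
            [1, 1, 1], [0.1, 0.2, 0.3], se_x=[0.01] * 3, se_y=[1, 1, 1])
        assert est.beta_ == pytest.approx(0.2)

    def test_interpolated_estimate_with_unequal_weights(self):
        # ratios (0.1, 0.3, 0.4), normalized weights (0.25, 0.25, 0.50)
        est = WeightedMedianEstimator(n_boot=50, seed=0).fit(
            [1, 1, 1], [0.1, 0.3, 0.4],
            se_x=[0.01] * 3, se_y=[1, 1, 1 / np.sqrt(2)])
        assert est.beta_ == pytest.approx(0.3 + 0.1 * (0.5 - 0.375) / 0.375)

    def test_constant_ratios_recovered_and_seed_invariant(self):
        bx = [0.02, 0.05, 0.08, 0.03]
        by = [0.01, 0.025, 0.04, 0.015]  # all ratios exactly 0.5
        fits = [WeightedMedianEstimator(n_boot=300, seed=s).fit(
                    bx, by, se_x=[0.001] * 4, se_y=[0.001] * 4)
                for s in (1, 2)]
        assert fits[0].beta_ == fits[1].beta_ == pytest.approx(0.5)
        assert fits[0].se_ < 0.1
        # only the bootstrap SE depends on the seed
        assert fits[0].se_ != fits[1].se_

    def test_permutation_invariance_of_estimate(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.02, 0.08, 5)
        by = rng.normal(0.5 * bx, 0.01)
        sy = rng.uniform(0.005, 0.02, 5)
        base = WeightedMedianEstimator(n_boot=10, seed=0).fit(
            bx, by, se_x=np.full(5, 0.005), se_y=sy).beta_
        perm = rng.permutation(5)
        shuffled = WeightedMedianEstimator(n_boot=10, seed=0).fit(
            bx[perm], by[perm], se_x=np.full(5, 0.005), se_y=sy[perm]).beta_
        assert shuffled == pytest.approx(base, abs=1e-14)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            WeightedMedianEstimator(n_boot=10, seed=0).fit(
                [0.02, 0.03], [0.01, 0.01], se_y=[0.01, 0.01])


class TestEgger:
    def test_exact_line_recovered(self):
        est = EggerRegression().fit([0.02, 0.04, 0.06], [0.015, 0.025, 0.035],
                                    se_y=[0.01] * 3)
        assert est.beta_ == pytest.approx(0.5)
        assert est.intercept_ == pytest.approx(0.005)

    def test_weighted_normal_equations_by_hand(self):
        est = EggerRegression().fit([0.02, 0.04, 0.06], [0.02, 0.025, 0.04],
                                    se_y=[0.01, 0.01, 0.02])
        assert est.beta_ == pytest.approx(5 / 12)
        assert est.intercept_ == pytest.approx(0.0105555555555, rel=1e-9)
        assert 0 < est.intercept_p_ < 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_zero_intercept_constraint_recovers_ivw_slope(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 10))
        bx = rng.uniform(-0.08, 0.08, k)
        bx[bx == 0] = 0.01
        by = rng.normal(0, 0.02, k)
        sy = rng.uniform(0.005, 0.03, k)
        constrained = EggerRegression(fix_intercept=True).fit(bx, by, se_y=sy)
        unweighted = IVWEstimator().fit(bx, by, se_y=sy)
        assert constrained.beta_ == pytest.approx(unweighted.beta_, rel=1e-12)
        assert constrained.se_ == pytest.approx(unweighted.se_, rel=1e-12)

    def test_orientation_invariance_to_allele_coding(self):
        bx = np.array([0.02, -0.04, 0.06])
        by = np.array([0.02, -0.025, 0.04])
        sy = np.array([0.01, 0.01, 0.02])
        a = EggerRegression().fit(bx, by, se_y=sy)
        flip = np.array([1, -1, 1.0])
        b = EggerRegression().fit(bx * flip, by * flip, se_y=sy)
        assert a.beta_ == pytest.approx(b.beta_)
        assert a.intercept_ == pytest.approx(b.intercept_)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            EggerRegression().fit([0.02, 0.03], [0.01, 0.01], se_y=[0.01, 0.01])

    def test_i2gx_truncates_at_zero_when_dispersion_is_sampling_noise(self):
        # exposure effects spread far less than their SEs: Q_GX < K - 1
        est = EggerRegression().fit([0.050, 0.051, 0.049], [0.02, 0.03, 0.025],
                                    se_x=[0.5] * 3, se_y=[0.01] * 3)
        assert est.q_gx_ < 2.0
        assert est.i2_gx_ == 0.0

    def test_i2gx_near_one_for_precise_heterogeneous_effects(self):
        est = EggerRegression().fit([0.02, 0.05, 0.09], [0.01, 0.02, 0.04],
                                    se_x=[0.0001] * 3, se_y=[0.01] * 3)
        assert est.i2_gx_ > 0.99


class TestSetLevelWrappersAndAPI:
    def test_wrappers_match_classes_and_carry_scale(self):
        hs = make_hset([0.02, 0.03, 0.06], [0.01, 0.012, 0.03],
                       [0.01, 0.01, 0.02], scale="log-odds")
        res = ivw(hs)
        assert res.method == "ivw"
        assert res.beta == pytest.approx(10.1 / 22)
        orr, lo, hi = res.odds_ratio()
        assert orr == pytest.approx(np.exp(res.beta))
        assert lo < orr < hi

        g = gls_correlated(hs)
        assert g.beta == pytest.approx(res.beta)  # identity LD

        wm = weighted_median(hs, n_boot=50, seed=1)
        assert wm.n_snps == 3

        eg, diag = egger(hs)
        assert eg.intercept is not None
        assert 0.0 <= diag.i2_gx <= 1.0

    def test_odds_ratio_refused_off_log_odds_scale(self):
        hs = make_hset([0.02, 0.03], [0.01, 0.012], [0.01, 0.01], scale="SD")
        with pytest.raises(ValueError, match="odds ratio"):
            ivw(hs).odds_ratio()

    def test_ci_brackets_estimate(self):
        hs = make_hset([0.02, 0.03], [0.01, 0.012], [0.01, 0.01])
        res = ivw(hs)
        assert res.ci_low < res.beta < res.ci_high

    def test_sklearn_clone_and_get_params(self):
        est = WeightedMedianEstimator(alpha=0.1, n_boot=77, seed=5)
        cloned = clone(est)
        assert cloned.get_params() == {"alpha": 0.1, "n_boot": 77, "seed": 5}
        assert clone(EggerRegression(fix_intercept=True)).fix_intercept
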