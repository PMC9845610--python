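"""Causal estimators: Wald ratio, IVW, MR-Egger, weighted median/mode."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from causalmr.estimators import (
    Z95,
    egger,
    ivw,
    or_scale,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from conftest import make_instruments


def _random_instruments(rng, j=None):
    j = j or rng.integers(2, 40)
    bx = rng.uniform(0.03, 0.3, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.003, 0.02, j)
    sy = rng.uniform(0.003, 0.05, j)
    by = 0.15 * bx + rng.normal(0, sy)
    return make_instruments(bx, by, sy, se_exp=sx)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,theta,se",
        [(0.10, 0.015, 0.005, 0.15, 0.05), (0.20, 0.030, 0.010, 0.15, 0.05)],
    )
    def test_arithmetic(self, bx, by, sy, theta, se):
        est = wald_ratio(make_instruments([bx], [by], [sy]))
        assert est.theta == pytest.approx(theta)
        assert est.se == pytest.approx(se)
        assert est.ci_low == pytest.approx(theta - Z95 * se)
        assert est.ci_high == pytest.approx(theta + Z95 * se)

    def test_null_outcome_gives_p_one(self):
        est = wald_ratio(make_instruments([0.1], [0.0], [0.01]))
        assert est.theta == 0.0 and est.pval == 1.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(make_instruments([0.0], [0.01], [0.01]))


class TestIVW:
    def test_hand_worked_two_instrument_example(self, two_instruments):
        fixed = ivw(two_instruments, effects_model="fixed")
        assert fixed.theta == pytest.approx(0.15, rel=1e-12)
        assert fixed.se == pytest.approx(np.sqrt(1 / 800), rel=1e-12)
        random = ivw(two_instruments, effects_model="random")
        assert random.theta == pytest.approx(0.15, rel=1e-12)
        assert random.se == pytest.approx(np.sqrt(1 / 800) * np.sqrt(2), rel=1e-12)

    def test_single_instrument_equals_wald_bitwise(self):
        one = make_instruments([0.137], [0.0213], [0.0071])
        w, i = wald_ratio(one), ivw(one)
        assert (i.theta, i.se, i.pval) == (w.theta, w.se, w.pval)

    def test_zero_heterogeneity_random_equals_fixed(self):
        insts = make_instruments(
            [0.1, 0.2, 0.3], [0.015, 0.030, 0.045], [0.005, 0.01, 0.02]
        )
        assert ivw(insts, "random").se == pytest.approx(ivw(insts, "fixed").se)
        assert ivw(insts, "fixed").theta == pytest.approx(0.15)

    def test_auto_switches_on_heterogeneity(self, two_instruments):
        # Q = 2.0, p ~ 0.157 -> fixed
        assert ivw(two_instruments, "auto").effects_model == "fixed"
        spread = make_instruments(
            [0.1] * 4, [0.001, 0.04, 0.001, 0.04], [0.003] * 4
        )
        assert ivw(spread, "auto").effects_model == "random"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ivw(make_instruments([], [], []))

    def test_matches_wls_oracle(self):
        """Brute-force origin-constrained weighted least squares via lstsq
        on 100 random instrument sets, 1e-10 relative agreement."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            insts = _random_instruments(rng)
            bx = insts["beta_exp"].to_numpy()
            by = insts["beta_out"].to_numpy()
            sy = insts["se_out"].to_numpy()
            sw = np.sqrt(bx**2 / sy**2) / np.abs(bx)  # row weight on (bx, by)
            coef, *_ = np.linalg.lstsq(
                (sw * bx)[:, None], sw * by, rcond=None
            )
            assert ivw(insts).theta == pytest.approx(coef[0], rel=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_scale_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        insts = _random_instruments(rng)
        scaled = insts.assign(beta_out=insts["beta_out"] * c, se_out=insts["se_out"] * c)
        assert ivw(scaled).theta == pytest.approx(c * ivw(insts).theta, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_orientation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        insts = _random_instruments(rng, j=12)
        flip = rng.choice([-1.0, 1.0], len(insts))
        flipped = insts.assign(
            beta_exp=insts["beta_exp"] * flip, beta_out=insts["beta_out"] * flip
        )
        assert ivw(flipped).theta == pytest.approx(ivw(insts).theta, rel=1e-9)
        assert egger(flipped)[0].theta == pytest.approx(egger(insts)[0].theta, rel=1e-9)
        wm_a = weighted_median(insts, n_boot=100, seed=1).theta
        wm_b = weighted_median(flipped, n_boot=100, seed=1).theta
        assert wm_b == pytest.approx(wm_a, rel=1e-9)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        insts = make_instruments(bx, 0.02 + 0.15 * bx, [0.01] * 4)
        slope, intercept = egger(insts)
        assert slope.theta == pytest.approx(0.15, rel=1e-9)
        assert intercept.theta == pytest.approx(0.02, rel=1e-9)
        assert slope.se > 0 and intercept.se > 0

    def test_all_null_outcome(self):
        insts = make_instruments([0.1, 0.2, 0.3], [0, 0, 0], [0.01] * 3)
        slope, intercept = egger(insts)
        assert slope.theta == pytest.approx(0.0, abs=1e-12)
        assert intercept.theta == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_instruments(self, two_instruments):
        with pytest.raises(ValueError, match=">= 3"):
            egger(two_instruments)

    def test_residual_scale_floored_at_one(self):
        """On an exact linear fit the multiplicative scale is 1, so the se
        equals the unscaled WLS se."""
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        insts = make_instruments(bx, 0.02 + 0.15 * bx, [0.01] * 4)
        slope, _ = egger(insts)
        w = np.full(4, 1e4)  # 1/se_y^2
        X = np.column_stack([np.ones(4), bx])
        cov = np.linalg.inv(X.T @ (w[:, None] * X))
        assert slope.se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-9)

    def test_directional_pleiotropy_intercept_recovery(self):
        """With InSIDE-respecting directional pleiotropy of mean 0.03, the
        mean intercept over replicates sits within 3 MC SEs of 0.03."""
        rng = np.random.default_rng(7)
        intercepts = []
        for _ in range(300):
            j = 20
            gamma = rng.uniform(0.05, 0.25, j)
            sy = np.full(j, 0.01)
            alpha = rng.normal(0.03, 0.01, j)
            by = 0.15 * gamma + alpha + rng.normal(0, sy)
            intercepts.append(egger(make_instruments(gamma, by, sy))[1].theta)
        mc_se = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert abs(np.mean(intercepts) - 0.03) < 3 * mc_se


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        insts = make_instruments([0.1] * 3, [0.010, 0.015, 0.020], [0.01] * 3)
        est = weighted_median(insts, n_boot=200, seed=0)
        assert est.theta == pytest.approx(0.15)

    def test_identical_ratios(self):
        insts = make_instruments([0.1, 0.2, 0.3], [0.02, 0.04, 0.06], [0.01] * 3)
        est = weighted_median(insts, n_boot=500, seed=0)
        assert est.theta == pytest.approx(0.2, rel=1e-12)
        assert est.se < 0.2

    def test_requires_three(self, two_instruments):
        with pytest.raises(ValueError):
            weighted_median(two_instruments, seed=0)

    def test_small_bootstrap_warns(self):
        insts = make_instruments([0.1] * 3, [0.01, 0.015, 0.02], [0.01] * 3)
        with pytest.warns(UserWarning):
            weighted_median(insts, n_boot=50, seed=0)

    def test_breakdown_under_majority_valid(self):
        """49% of weight on a contaminating ratio 0.8 leaves the estimate
        at the valid ratio ~0.15; identical draw with 51% contamination
        drags it to 0.8."""
        rng = np.random.default_rng(5)
        j = 100
        bx = np.full(j, 0.1)
        sy = np.full(j, 0.001)
        noise = rng.normal(0, 0.02, j)

        def estimate(n_bad):
            ratios = np.where(np.arange(j) < n_bad, 0.8, 0.15) + noise
            insts = make_instruments(bx, ratios * bx, sy)
            return weighted_median(insts, n_boot=100, seed=1).theta

        assert abs(estimate(49) - 0.15) < 0.05
        assert abs(estimate(51) - 0.8) < 0.05


class TestWeightedMode:
    def test_dominant_cluster_wins(self):
        insts = make_instruments(
            [0.1] * 4, [0.015, 0.015, 0.015, 0.080], [0.01] * 4
        )
        est = weighted_mode(insts, n_boot=200, seed=0)
        # within one grid step of the dominant cluster's ratio
        assert abs(est.theta - 0.15) < 0.01

    def test_identical_ratios(self):
        insts = make_instruments([0.1, 0.2, 0.4], [0.02, 0.04, 0.08], [0.01] * 3)
        est = weighted_mode(insts, n_boot=200, seed=0)
        assert est.theta == pytest.approx(0.2, rel=1e-12)

    def test_symmetric_clusters_tie_breaks_low(self):
        insts = make_instruments(
            [0.1] * 6, [0.01] * 3 + [0.02] * 3, [0.01] * 6
        )
        est = weighted_mode(insts, n_boot=100, seed=0)
        # lands on one of the two cluster modes (exact density ties break to
        # the smaller grid value via first-maximum selection)
        assert min(abs(est.theta - 0.1), abs(est.theta - 0.2)) < 0.02

    def test_requires_three(self, two_instruments):
        with pytest.raises(ValueError):
            weighted_mode(two_instruments, seed=0)


class TestORScale:
    def test_null_effect_maps_to_unit_or(self):
        est = wald_ratio(make_instruments([0.1], [0.0], [0.01]))
        orr = or_scale(est)
        assert orr.or_ == pytest.approx(1.0)

    def test_log_odds_to_or_roundtrip(self):
        """θ = 0.13174, se = 0.03675 corresponds to OR 1.1408 with 95% CI
        (1.0614, 1.2261) at printed precision."""
        theta, se = 0.13174, 0.03675
        est = wald_ratio(make_instruments([1.0], [theta], [se]))
        orr = or_scale(est)
        assert orr.or_ == pytest.approx(1.1408, abs=5e-4)
        assert orr.ci_low == pytest.approx(1.0614, abs=1e-3)
        assert orr.ci_high == pytest.approx(1.2261, abs=1e-3)

    def test_negative_effect(self):
        est = wald_ratio(make_instruments([1.0], [-0.1], [0.051]))
        orr = or_scale(est)
        assert orr.or_ == pytest.approx(np.exp(-0.1), rel=1e-12)
        assert orr.ci_low == pytest.approx(np.exp(est.ci_low), rel=1e-12)

    def test_bounds_ordered(self):
        est = wald_ratio(make_instruments([0.2], [0.03], [0.01]))
        orr = or_scale(est)
        assert orr.ci_low <= orr.or_ <= orr.ci_high


def test_bootstrap_seed_reproducibility():
    rng = np.random.default_rng(3)
    insts = _random_instruments(rng, j=10)
    a = weighted_median(insts, n_boot=300, seed=9)
    b = weighted_median(insts, n_boot=300, seed=9)
    assert a.se == b.se
    c = weighted_mode(insts, n_boot=300, seed=9)
    d = weighted_mode(insts, n_boot=300, seed=9)
    assert c.se == d.se
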