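"""Conditional logistic likelihood: closed-form oracles and invariants."""

import numpy as np
import pytest

from ihcrisk import (
    PairDesign,
    SeparationError,
    fit_clogit,
    lrt,
    pair_loglik,
    predict_risk_curve,
    simulate_matched_pairs,
    wald_or_ci,
)
from ihcrisk.matched_inference import NotConvergedError, NotIdentifiableError

LN3 = np.log(3.0)


def design(*rows, names=None):
    arr = np.atleast_2d(np.array(rows, dtype=float))
    if arr.shape[0] == 1 and len(rows) > 1:
        arr = arr.T
    names = names or [f"x{j}" for j in range(arr.shape[1])]
    return PairDesign(arr, names)


class TestPairLoglik:
    def test_beta_zero_gives_n_ln2(self):
        d = design(1.0, -1.0, 0.5, 2.0)
        assert pair_loglik(d, [0.0]) == pytest.approx(-4 * np.log(2))

    def test_zero_difference_pair_uninformative(self):
        d = design(0.0)
        for beta in (-3.0, 0.0, 5.0):
            assert pair_loglik(d, [beta]) == pytest.approx(-np.log(2))

    def test_direct_evaluation(self):
        # diffs (1,1,1,-1), beta=ln3: l = -3 ln(4/3) - ln 4
        d = design(1.0, 1.0, 1.0, -1.0)
        expected = -3 * np.log(4 / 3) - np.log(4)
        assert pair_loglik(d, [LN3]) == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            pair_loglik(design(1.0), [np.inf])


class TestFitClogit:
    def test_three_up_one_down(self):
        # stationarity: 3 - 4p = 0 -> p = 3/4 -> beta = ln 3;
        # observed information 4 * p(1-p) -> se = 1/sqrt(0.75)
        fit = fit_clogit(design(1.0, 1.0, 1.0, -1.0))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(LN3, abs=1e-8)
        assert fit.se(0) == pytest.approx(1.0 / np.sqrt(4 * 0.75 * 0.25), abs=1e-6)

    def test_mirrored_design_gives_zero(self):
        fit = fit_clogit(design(1.0, -1.0, 0.7, -0.7, 2.0, -2.0))
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)

    def test_mcnemar_identity_exact(self, rng):
        # single binary covariate: OR = n(+1) / n(-1) exactly
        for _ in range(10):
            n_pos = int(rng.integers(2, 15))
            n_neg = int(rng.integers(2, 15))
            d = design(*([1.0] * n_pos + [-1.0] * n_neg))
            fit = fit_clogit(d)
            assert np.exp(fit.beta[0]) == pytest.approx(n_pos / n_neg, rel=1e-7)

    def test_label_swap_antisymmetry(self, rng):
        d = PairDesign(rng.standard_normal((40, 2)), ["a", "b"])
        fit = fit_clogit(d)
        flipped = fit_clogit(PairDesign(-d.diffs, d.names))
        assert flipped.beta == pytest.approx(-fit.beta, abs=1e-7)
        assert flipped.loglik == pytest.approx(fit.loglik, abs=1e-9)

    def test_grid_search_agreement(self, rng):
        # independent oracle: brute-force 1-D grid over [-5, 5]
        for _ in range(5):
            diffs = np.sign(rng.standard_normal(15)) * rng.uniform(0.5, 1.5, 15)
            d = PairDesign(diffs[:, None], ["x"])
            grid = np.arange(-5.0, 5.0, 1e-3)
            lls = np.array([pair_loglik(d, [b]) for b in grid])
            best = grid[np.argmax(lls)]
            if abs(best) > 4.5:  # near-separated draw; oracle unreliable
                continue
            fit = fit_clogit(d)
            assert abs(fit.beta[0] - best) < 1e-3

    def test_all_zero_column_not_identifiable(self):
        d = PairDesign(np.array([[1.0, 0.0], [-1.0, 0.0]]), ["good", "flat"])
        with pytest.raises(NotIdentifiableError, match="flat"):
            fit_clogit(d)

    def test_complete_separation_raises(self):
        d = design(*([1.0] * 12))
        with pytest.raises(SeparationError):
            fit_clogit(d)

    def test_statsmodels_cross_check(self, rng):
        # 1:1 conditional likelihood == intercept-free logit with all
        # outcomes 1 on the differences
        sm = pytest.importorskip("statsmodels.api")
        d = PairDesign(rng.standard_normal((200, 3)) + 0.2, ["a", "b", "c"])
        fit = fit_clogit(d)
        ref = sm.Logit(np.ones(d.n_pairs), d.diffs).fit(disp=0)
        assert fit.beta == pytest.approx(ref.params, abs=1e-6)
        assert [fit.se(j) for j in range(3)] == pytest.approx(ref.bse, abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)


class TestWaldOrCi:
    def test_null_coefficient(self):
        fit = fit_clogit(design(1.0, -1.0, 0.5, -0.5))
        or_, lo, hi, p = wald_or_ci(fit, 0)
        assert or_ == pytest.approx(1.0)
        assert np.log(lo) == pytest.approx(-np.log(hi), abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_known_interval(self):
        fit = fit_clogit(design(1.0, 1.0, 1.0, -1.0))
        or_, lo, hi, _ = wald_or_ci(fit, "x0")
        # exp(ln 3 -+ 1.96 * 1.1547)
        assert or_ == pytest.approx(3.0, abs=1e-6)
        assert lo == pytest.approx(0.312, abs=0.002)
        assert hi == pytest.approx(28.85, abs=0.15)

    def test_wider_level_contains_narrower(self):
        fit = fit_clogit(design(1.0, 1.0, -1.0, 1.0, -1.0, 1.0))
        _, lo95, hi95, _ = wald_or_ci(fit, 0, level=0.95)
        _, lo99, hi99, _ = wald_or_ci(fit, 0, level=0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_refuses_unconverged(self):
        fit = fit_clogit(design(1.0, -1.0))
        bad = type(fit)(fit.beta, fit.covariance, fit.loglik, False, 50, fit.names, fit.n_pairs)
        with pytest.raises(NotConvergedError):
            wald_or_ci(bad, 0)


class TestLrt:
    def test_identical_models(self, rng):
        d = PairDesign(rng.standard_normal((30, 1)), ["x"])
        fit = fit_clogit(d)
        res = lrt(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.df == 0

    def test_statistic_nonnegative_over_random_nested_fits(self, rng):
        for _ in range(100):
            d = PairDesign(rng.standard_normal((25, 2)) * 0.8, ["a", "b"])
            full = fit_clogit(d)
            reduced = fit_clogit(d.subset(["a"]))
            assert lrt(full, reduced).statistic >= 0.0

    def test_non_nested_rejected(self, rng):
        d = PairDesign(rng.standard_normal((30, 2)), ["a", "b"])
        fa = fit_clogit(d.subset(["a"]))
        fb = fit_clogit(d.subset(["b"]))
        with pytest.raises(ValueError):
            lrt(fa, fb)

    def test_df_counts_parameter_difference(self, rng):
        d = PairDesign(rng.standard_normal((60, 3)) * 0.5, ["a", "b", "c"])
        res = lrt(fit_clogit(d), fit_clogit(d.subset(["a"])))
        assert res.df == 2


class TestPredictRiskCurve:
    def fit_with(self, beta_lin, beta_quad, rng):
        g = rng.standard_normal(300)
        g2 = g**2
        d = np.column_stack([g - rng.standard_normal(300), g2 - rng.standard_normal(300) ** 2])
        # fabricate a FitResult directly: prediction only reads beta/names
        from ihcrisk.matched_inference import FitResult

        return FitResult(
            beta=np.array([beta_lin, beta_quad]),
            covariance=np.eye(2),
            loglik=0.0,
            converged=True,
            n_iter=1,
            names=["g", "g_sq"],
            n_pairs=300,
        )

    def test_quadratic_zero_is_loglinear(self, rng):
        fit = self.fit_with(0.3, 0.0, rng)
        grid = np.linspace(-2, 2, 41)
        curve = predict_risk_curve(fit, grid, 0.0, "g", "g_sq")
        assert np.allclose(np.diff(np.log(curve)), 0.3 * np.diff(grid))

    def test_pure_quadratic_u_shape(self, rng):
        fit = self.fit_with(0.0, 0.4, rng)
        grid = np.linspace(-2, 2, 41)
        curve = predict_risk_curve(fit, grid, 0.0, "g", "g_sq")
        assert np.argmin(curve) == 20  # minimum at the (centred) mean
        assert curve[0] > 1 and curve[-1] > 1

    def test_normalised_at_mean(self, rng):
        fit = self.fit_with(0.2, 0.1, rng)
        curve = predict_risk_curve(fit, np.array([0.7]), 0.7, "g", "g_sq")
        assert curve[0] == pytest.approx(1.0)

    def test_missing_marker_term_rejected(self, rng):
        fit = self.fit_with(0.2, 0.1, rng)
        with pytest.raises(ValueError):
            predict_risk_curve(fit, np.array([0.0]), 0.0, "absent")


class TestParameterRecoverySmoke:
    def test_pair_simulation_recovers_truth(self):
        # quick version of the full recovery study (deeper run in the
        # acceptance suite)
        est = []
        for seed in range(20):
            d = simulate_matched_pairs(400, [np.log(0.85)], seed=seed)
            est.append(fit_clogit(d).beta[0])
        assert np.mean(est) == pytest.approx(np.log(0.85), abs=0.05)
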