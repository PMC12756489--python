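"""Logistic fitting, odds-ratio inference, and calibration."""

import numpy as np
import pytest
from scipy import optimize, stats

import srflex
from srflex.features import DesignMatrix
from srflex.risk_model import ModelError, SeparationError


def design_2x2():
    # cell counts: (x=1,y=1)=10, (x=1,y=0)=5, (x=0,y=1)=20, (x=0,y=0)=40
    X = np.array([[1.0]] * 15 + [[0.0]] * 60)
    y = np.array([1] * 10 + [0] * 5 + [1] * 20 + [0] * 40)
    return DesignMatrix.from_arrays(X, y, ["x"])


def random_design(rng, n=150, p=3):
    X = rng.poisson(1.0, size=(n, p)).astype(float)
    beta = np.array([0.4, -0.3, 0.2][:p])
    eta = X @ beta - 1.0
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return DesignMatrix.from_arrays(X, y, [f"c{j}" for j in range(p)])


class TestFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 17 + [0] * 83)
        design = DesignMatrix.from_arrays(np.empty((100, 0)), y, [])
        fit = srflex.fit_logistic(design)
        assert fit.coef[0] == pytest.approx(np.log(0.17 / 0.83), abs=1e-10)
        p = srflex.predict_proba(fit, design)
        assert np.allclose(p, 0.17)

    def test_2x2_cross_product_ratio(self):
        fit = srflex.fit_logistic(design_2x2())
        assert np.exp(fit.coef[0]) == pytest.approx(4.0, abs=1e-6)
        se_hand = np.sqrt(1 / 10 + 1 / 5 + 1 / 20 + 1 / 40)
        assert fit.se[0] == pytest.approx(se_hand, rel=1e-6)

    def test_matches_generic_numerical_maximizer(self, rng):
        design = random_design(rng)
        fit = srflex.fit_logistic(design)

        def nll(beta):
            eta = design.X @ beta
            return -(design.y @ eta - np.logaddexp(0, eta).sum())

        res = optimize.minimize(nll, np.zeros(design.X.shape[1]),
                                method="BFGS", options={"gtol": 1e-10})
        assert np.allclose(fit.coef, res.x, atol=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        design = random_design(rng, n=200)
        fit = srflex.fit_logistic(design)
        sm_fit = sm.Logit(design.y, design.X).fit(disp=0)
        assert np.allclose(fit.coef, sm_fit.params, atol=1e-6)
        assert np.allclose(fit.se, sm_fit.bse, rtol=1e-4)

    def test_row_permutation_invariance(self, rng):
        design = random_design(rng)
        perm = rng.permutation(design.n_obs)
        permuted = DesignMatrix(design.X[perm], design.y[perm],
                                design.column_names,
                                [design.session_ids[i] for i in perm])
        assert np.allclose(srflex.fit_logistic(design).coef,
                           srflex.fit_logistic(permuted).coef, atol=1e-8)

    def test_separation_detected_and_flagged(self):
        X = np.array([[1.0]] * 10 + [[-1.0]] * 10)
        y = np.array([1] * 10 + [0] * 10)
        fit = srflex.fit_logistic(DesignMatrix.from_arrays(X, y, ["x"]))
        assert fit.separation_detected
        with pytest.raises(SeparationError):
            srflex.effects_table(fit)
        with pytest.raises(SeparationError):
            _ = fit.se

    def test_single_class_errors(self):
        design = DesignMatrix.from_arrays(np.ones((5, 1)), [1] * 5, ["x"])
        with pytest.raises(ModelError, match="both classes"):
            srflex.fit_logistic(design)

    def test_constant_column_errors(self):
        X = np.column_stack([np.full(10, 2.0)])
        y = [0, 1] * 5
        with pytest.raises(ModelError, match="constant"):
            srflex.fit_logistic(DesignMatrix.from_arrays(X, y, ["c"]))


class TestEffects:
    def test_null_effect(self):
        fit = srflex.LogisticFit(
            coef=np.array([0.0, -1.0]), cov=np.diag([0.01, 0.01]),
            loglik=0.0, converged=True, n_iter=1, separation_detected=False,
            column_names=["x", "intercept"], n_obs=100)
        (eff,) = srflex.effects_table(fit)
        assert eff.odds_ratio == pytest.approx(1.0)
        assert eff.ci_low == pytest.approx(np.exp(-1.959964 * 0.1), rel=1e-5)
        assert eff.ci_high == pytest.approx(np.exp(1.959964 * 0.1), rel=1e-5)
        assert not eff.significant

    def test_2x2_wald_ci_matches_hand_formula(self):
        fit = srflex.fit_logistic(design_2x2())
        (eff,) = srflex.effects_table(fit)
        se = np.sqrt(1 / 10 + 1 / 5 + 1 / 20 + 1 / 40)
        z = stats.norm.ppf(0.975)
        assert eff.ci_low == pytest.approx(np.exp(np.log(4) - z * se), rel=1e-5)
        assert eff.ci_high == pytest.approx(np.exp(np.log(4) + z * se), rel=1e-5)

    def test_significance_iff_ci_excludes_one(self, rng):
        design = random_design(rng, n=300)
        effects = srflex.effects_table(srflex.fit_logistic(design))
        for eff in effects:
            excludes = eff.ci_low > 1.0 or eff.ci_high < 1.0
            assert eff.significant == excludes

    def test_intercept_excluded(self, rng):
        effects = srflex.effects_table(srflex.fit_logistic(random_design(rng)))
        assert all(e.category_id != "intercept" for e in effects)

    def test_bh_correction_is_more_conservative(self, rng):
        design = random_design(rng, n=120)
        fit = srflex.fit_logistic(design)
        raw = srflex.effects_table(fit)
        adj = srflex.effects_table(fit, bh_correction=True)
        assert sum(e.significant for e in adj) <= sum(e.significant for e in raw)


class TestPredict:
    def test_column_mismatch_errors(self, rng):
        design = random_design(rng)
        fit = srflex.fit_logistic(design)
        other = DesignMatrix.from_arrays(design.X[:, :-1], design.y,
                                         ["a", "b", "c"])
        with pytest.raises(ModelError, match="columns"):
            srflex.predict_proba(fit, other)

    def test_hand_computed_sigmoid(self):
        fit = srflex.LogisticFit(
            coef=np.array([0.5, -1.0]), cov=np.eye(2), loglik=0.0,
            converged=True, n_iter=1, separation_detected=False,
            column_names=["x", "intercept"], n_obs=3)
        X = np.array([[0.0, 1.0], [1.0, 1.0], [4.0, 1.0]])
        design = DesignMatrix(X, np.array([0, 1, 1]), ["x", "intercept"],
                              ["a", "b", "c"])
        p = srflex.predict_proba(fit, design)
        expected = 1 / (1 + np.exp(-(np.array([0.0, 1.0, 4.0]) * 0.5 - 1.0)))
        assert np.allclose(p, expected)


class TestHosmerLemeshow:
    def test_published_reference_pvalue(self):
        assert srflex.calibration_pvalue(11.21, 8) == pytest.approx(0.19, abs=0.005)

    def test_well_specified_model_rejection_rate(self, rng):
        # outcome simulated from the fitted model's own law: HL should
        # reject at roughly the nominal 5% rate
        rejections = 0
        reps = 60
        for _ in range(reps):
            X = rng.normal(size=(2000, 2))
            eta = X @ np.array([0.8, -0.5]) - 1.0
            y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(int)
            design = DesignMatrix.from_arrays(X, y, ["a", "b"])
            fit = srflex.fit_logistic(design)
            res = srflex.hosmer_lemeshow(fit, design)
            assert res.df == 8
            rejections += res.p_value < 0.05
        assert rejections / reps < 0.15

    def test_too_few_observations_error(self, rng):
        X = rng.normal(size=(5, 1))
        y = [0, 1, 0, 1, 0]
        design = DesignMatrix.from_arrays(X, y, ["x"])
        fit = srflex.fit_logistic(design)
        with pytest.raises(ValueError, match="at least 10"):
            srflex.hosmer_lemeshow(fit, design, groups=10)

    def test_ties_stay_in_one_bin(self):
        # intercept-only fit gives identical predictions: all ties collapse
        # into a single bin, leaving the others with zero expected counts
        y = np.array([1] * 20 + [0] * 80)
        design = DesignMatrix.from_arrays(np.empty((100, 0)), y, [])
        fit = srflex.fit_logistic(design)
        with pytest.raises(ValueError, match="fewer groups"):
            srflex.hosmer_lemeshow(fit, design)
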