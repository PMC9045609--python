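"""Logistic fitter vs closed forms, statsmodels and a grid oracle; the
stepwise and hierarchical selection machinery; fit diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from lumbarcpr import (
    VariableClass,
    adequacy_ranks,
    backward_eliminate,
    fit_logistic,
    hierarchical_modeling,
    hosmer_lemeshow,
    nagelkerke_r2,
)
from lumbarcpr.modeling import ModelingConfig, RankDeficiencyError, _deviance, _intercept_only


def _sim_design(rng, n=300, betas=(0.8, -0.6, 1.1), intercept=-0.3):
    X = pd.DataFrame(
        {f"x{i}": rng.normal(size=n) for i in range(len(betas))}
    )
    eta = intercept + X.to_numpy() @ np.array(betas)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 54 + [0.0] * 45)
        fit = fit_logistic(pd.DataFrame(index=range(99)), y)
        assert fit.intercept == pytest.approx(math.log(54 / 45), abs=1e-8)

    def test_single_binary_predictor_equals_log_odds_ratio(self):
        tp, fp, fn, tn = 30, 10, 12, 28
        x = [1.0] * (tp + fp) + [0.0] * (fn + tn)
        y = [1.0] * tp + [0.0] * fp + [1.0] * fn + [0.0] * tn
        fit = fit_logistic(pd.DataFrame({"t": x}), np.array(y))
        assert fit.term("t").b == pytest.approx(math.log(tp * tn / (fp * fn)), abs=1e-8)
        assert fit.intercept == pytest.approx(math.log(fn / tn), abs=1e-8)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X, y = _sim_design(rng)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params["const"], abs=1e-6)
        for name in X.columns:
            assert fit.term(name).b == pytest.approx(ref.params[name], abs=1e-6)
            assert fit.term(name).se == pytest.approx(ref.bse[name], rel=1e-4)
        assert fit.minus2ll == pytest.approx(-2 * ref.llf, abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        """Brute-force likelihood maximization over a refined (b0, b1) grid
        agrees with IRLS to 1e-3."""
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + 1.2 * x)))).astype(float)

        def nll(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

        b0g, b1g = np.meshgrid(np.linspace(-3, 3, 61), np.linspace(-3, 3, 61))
        center = None
        for _ in range(6):  # coarse-to-fine refinement
            vals = np.vectorize(nll)(b0g, b1g)
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            center = (b0g[i, j], b1g[i, j])
            span = (b0g[0, 1] - b0g[0, 0]) * 2
            b0g, b1g = np.meshgrid(
                np.linspace(center[0] - span, center[0] + span, 41),
                np.linspace(center[1] - span, center[1] + span, 41),
            )
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.intercept == pytest.approx(center[0], abs=1e-3)
        assert fit.term("x").b == pytest.approx(center[1], abs=1e-3)

    def test_wald_ci_self_consistency(self, rng):
        X, y = _sim_design(rng, n=250)
        fit = fit_logistic(X, y)
        for t in fit.terms:
            lo, hi = t.ci95
            assert (hi - lo) / 3.919927969 == pytest.approx(t.se, rel=1e-6)

    def test_separation_flagged_not_raised(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.copy()
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.separation and not fit.converged

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(50) < 0.5).astype(float)
        y[:2] = [0.0, 1.0]
        with pytest.raises(RankDeficiencyError) as err:
            fit_logistic(X, y)
        assert set(err.value.columns) & {"a", "b"}

    def test_deviance_monotone_in_nesting(self, rng):
        X, y = _sim_design(rng)
        null = _intercept_only(y)
        d_prev, r_prev = null.minus2ll, 0.0
        for k in range(1, 4):
            fit = fit_logistic(X.iloc[:, :k], y)
            assert fit.minus2ll <= d_prev + 1e-8
            r2 = nagelkerke_r2(fit, null.minus2ll)
            assert r2 >= r_prev - 1e-12
            d_prev, r_prev = fit.minus2ll, r2


class TestNagelkerke:
    def test_null_fit_is_zero(self, rng):
        _, y = _sim_design(rng)
        null = _intercept_only(y)
        assert nagelkerke_r2(null, null.minus2ll) == pytest.approx(0.0)

    def test_formula_recomputation(self, rng):
        X, y = _sim_design(rng)
        null = _intercept_only(y)
        fit = fit_logistic(X, y)
        n = len(y)
        expected = (1 - math.exp((fit.minus2ll - null.minus2ll) / n)) / (
            1 - math.exp(-null.minus2ll / n)
        )
        assert nagelkerke_r2(fit, null.minus2ll) == pytest.approx(expected)
        assert 0 <= expected < 1


class TestHosmerLemeshow:
    def test_calibrated_null_rejection_rate(self):
        """Perfectly calibrated risks: ~5% rejection at alpha=.05."""
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 200
        for _ in range(reps):
            p = rng.uniform(0.05, 0.95, 1000)
            y = (rng.random(1000) < p).astype(float)
            res = hosmer_lemeshow(p, y)
            rejections += res.p < 0.05
        assert 0.01 <= rejections / reps <= 0.12

    def test_miscalibrated_has_power(self):
        rng = np.random.default_rng(78)
        rejections = 0
        reps = 50
        for _ in range(reps):
            p = rng.uniform(0.05, 0.95, 1000)
            y = (rng.random(1000) < p**2).astype(float)  # true risk != stated
            res = hosmer_lemeshow(p, y)
            rejections += res.p < 0.05
        assert rejections / reps > 0.5

    def test_few_distinct_risks_skipped(self):
        p = np.array([0.2, 0.8] * 50)
        y = (np.arange(100) % 2).astype(float)
        res = hosmer_lemeshow(p, y)
        assert res.skipped

    def test_zero_expected_bins_merged(self):
        rng = np.random.default_rng(79)
        # many risks at ~0 force empty expected-event bins
        p = np.concatenate([np.full(50, 1e-12), rng.uniform(0.2, 0.9, 50)])
        y = (rng.random(100) < p).astype(float)
        res = hosmer_lemeshow(p, y)
        assert res.skipped or res.df == res.n_bins - 2


class TestAdequacy:
    def test_single_term_is_one_rank_one(self, rng):
        X, y = _sim_design(rng, betas=(1.0,))
        fit = fit_logistic(X, y)
        ((name, adequacy, rank),) = adequacy_ranks(X, y, fit)
        assert adequacy == pytest.approx(1.0, abs=1e-9)
        assert rank == 1

    def test_symmetric_predictors_share_rank(self):
        rows = []
        # counts symmetric under swapping the two tests
        for a, b, n1, n0 in [(0, 0, 5, 20), (0, 1, 12, 13), (1, 0, 12, 13), (1, 1, 20, 5)]:
            rows += [(a, b, 1.0)] * n1 + [(a, b, 0.0)] * n0
        df = pd.DataFrame(rows, columns=["t1", "t2", "y"])
        fit = fit_logistic(df[["t1", "t2"]], df["y"].to_numpy())
        ranks = adequacy_ranks(df[["t1", "t2"]], df["y"].to_numpy(), fit)
        (n1, a1, r1), (n2, a2, r2) = ranks
        assert a1 == pytest.approx(a2, abs=1e-9)
        assert r1 == r2 == 1

    def test_matches_refit_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X, y = _sim_design(rng)
        fit = fit_logistic(X, y)
        null_dev = -2 * sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
        full_dev = -2 * sm.Logit(y, sm.add_constant(X)).fit(disp=0).llf
        for name, adequacy, _ in adequacy_ranks(X, y, fit):
            single_dev = -2 * sm.Logit(y, sm.add_constant(X[[name]])).fit(disp=0).llf
            expected = (null_dev - single_dev) / (null_dev - full_dev)
            assert adequacy == pytest.approx(expected, abs=1e-6)


class TestBackwardElimination:
    def test_forced_term_never_removed(self, rng):
        X, y = _sim_design(rng, betas=(0.0, 0.0, 0.9))
        res = backward_eliminate(X, y, pool=["x0", "x1", "x2"], forced_stay=["x0"])
        assert "x0" in res.final_fit.term_names

    def test_pure_noise_mostly_eliminated(self):
        empties = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            X, y = _sim_design(rng, betas=(0.0,) * 5)
            res = backward_eliminate(X, y, pool=list(X.columns))
            empties += not res.final_fit.term_names
        assert empties / reps >= 0.5

    def test_planted_term_retained(self):
        kept = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(2000 + seed)
            n = 400
            X = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(5)})
            X["planted"] = (rng.random(n) < 0.4).astype(float)
            eta = -1.0 + math.log(6.0) * X["planted"].to_numpy()
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            res = backward_eliminate(X, y, pool=list(X.columns))
            kept += "planted" in res.final_fit.term_names
        assert kept / reps >= 0.9

    def test_all_retained_terms_significant(self, rng):
        X, y = _sim_design(rng, n=400, betas=(1.0, 0.0, 0.8, 0.0, 0.0))
        res = backward_eliminate(X, y, pool=list(X.columns), alpha_retain=0.05)
        assert all(t.wald_p < 0.05 for t in res.final_fit.terms)

    def test_column_order_invariance(self, rng):
        X, y = _sim_design(rng, n=350, betas=(0.9, 0.1, -0.7))
        a = backward_eliminate(X, y, pool=["x0", "x1", "x2"])
        b = backward_eliminate(X[["x2", "x0", "x1"]], y, pool=["x2", "x0", "x1"])
        assert sorted(a.final_fit.term_names) == sorted(b.final_fit.term_names)
        for name in a.final_fit.term_names:
            assert a.final_fit.term(name).b == pytest.approx(
                b.final_fit.term(name).b, abs=1e-8
            )


class TestHierarchical:
    def _data(self, rng, with_b_effect=False):
        n = 400
        X = pd.DataFrame(
            {
                "testA1": (rng.random(n) < 0.4).astype(float),
                "testA2": (rng.random(n) < 0.5).astype(float),
                "testB1": (rng.random(n) < 0.5).astype(float),
                "testC1": rng.normal(size=n),
                "age": rng.normal(45, 12, n),
                "sex_female": (rng.random(n) < 0.5).astype(float),
                "bmi": rng.normal(26, 4, n),
            }
        )
        eta = -1.5 + 1.6 * X["testA1"] + 1.4 * X["testA2"]
        if with_b_effect:
            eta = eta + 1.2 * X["testB1"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        classes = {
            "testA1": VariableClass.A,
            "testA2": VariableClass.A,
            "testB1": VariableClass.B,
            "testC1": VariableClass.C,
        }
        return X, y, classes

    def test_steps_nest_and_reuse_survivors(self, rng):
        X, y, classes = self._data(rng, with_b_effect=True)
        steps = hierarchical_modeling(X, y, classes)
        assert [s.step for s in steps] == ["A_only", "A_plus_B", "A_plus_B_plus_C"]
        a_terms = set(steps[0].final_fit.term_names)
        assert {"testA1", "testA2"} <= a_terms
        assert "testB1" in steps[1].final_fit.term_names
        # class-B candidates never appear in step 1
        assert "testB1" not in steps[0].candidate_pool

    def test_no_accepted_bc_steps_collapse(self, rng):
        X, y, classes = self._data(rng)
        classes = {k: v for k, v in classes.items() if v is VariableClass.A}
        steps = hierarchical_modeling(X[["testA1", "testA2", "age", "sex_female", "bmi"]],
                                      y, classes)
        assert steps[0].final_fit.term_names == steps[1].final_fit.term_names
        assert steps[1].final_fit.term_names == steps[2].final_fit.term_names
        assert steps[0].final_fit.minus2ll == pytest.approx(steps[2].final_fit.minus2ll)

    def test_forced_confounders_stay(self, rng):
        X, y, classes = self._data(rng)
        steps = hierarchical_modeling(
            X, y, classes, ModelingConfig(force_confounders=True)
        )
        assert {"age", "sex_female", "bmi"} <= set(steps[0].final_fit.term_names)
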