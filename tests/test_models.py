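import warnings

import numpy as np
import pandas as pd
import pytest

from trialcea.errors import ConfigurationError, ModelError
from trialcea.models import (
    CeaEstimates,
    ModelSpec,
    estimate_cea_effects,
    fit_lmm,
    fit_logistic_mixed,
    fit_random_intercept,
)


def make_panel(n_per_arm, weeks, outcome_fn, rng):
    rows = []
    pid = 0
    for arm, treat in (("blended", 1.0), ("standard", 0.0)):
        for _ in range(n_per_arm):
            pid += 1
            for week in weeks:
                rows.append(
                    {
                        "patient_id": pid,
                        "arm": arm,
                        "treat": treat,
                        "week": week,
                        "y": outcome_fn(treat, week, pid, rng),
                    }
                )
    return pd.DataFrame(rows)


class TestFastRandomIntercept:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(17)
        b = {i: rng.normal(0, 2.0) for i in range(1, 81)}
        df = make_panel(
            40,
            (10, 20, 30),
            lambda t, w, pid, r: 3.0 + 1.2 * t + 0.05 * w + b[pid] + r.normal(0, 1.5),
            rng,
        )
        df["x"] = rng.normal(size=len(df))
        df["y"] = df["y"] + 0.4 * df["x"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm("y ~ treat + x", df, groups=df["patient_id"]).fit(
                reml=True
            )
        X = np.column_stack([np.ones(len(df)), df["treat"], df["x"]])
        got = fit_random_intercept(
            X, df["y"].to_numpy(), df["patient_id"].to_numpy(), ["Intercept", "treat", "x"]
        )
        assert np.allclose(got.params.to_numpy(), ref.fe_params.to_numpy(), atol=1e-6)
        assert np.allclose(got.bse.to_numpy(), ref.bse_fe.to_numpy(), atol=1e-3)
        assert got.var_e == pytest.approx(ref.scale, abs=1e-4)

    def test_perfect_fit_returns_exact_beta(self):
        rng = np.random.default_rng(0)
        df = make_panel(10, (10, 20), lambda t, w, pid, r: 2.0 + 0.7 * t, rng)
        X = np.column_stack([np.ones(len(df)), df["treat"]])
        got = fit_random_intercept(X, df["y"].to_numpy(), df["patient_id"].to_numpy())
        assert got.params.iloc[1] == pytest.approx(0.7, abs=1e-10)
        assert got.var_e == 0.0

    def test_singular_design_raises(self):
        X = np.ones((10, 2))  # duplicated column
        with pytest.raises(ModelError, match="singular"):
            fit_random_intercept(X, np.arange(10.0), np.arange(10) // 2)

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(1)
        df = make_panel(15, (10, 20), lambda t, w, pid, r: t + r.normal(), rng)
        y = df["y"].to_numpy().copy()
        y[::5] = np.nan
        X = np.column_stack([np.ones(len(df)), df["treat"]])
        got = fit_random_intercept(X, y, df["patient_id"].to_numpy())
        assert got.n_obs == np.isfinite(y).sum()


class TestFitLmm:
    def test_single_time_balanced_equals_mean_difference(self):
        rng = np.random.default_rng(5)
        df = make_panel(30, (10,), lambda t, w, pid, r: 1.0 + 0.9 * t + r.normal(), rng)
        est = fit_lmm(df, ModelSpec(outcome="y"))
        means = df.groupby("treat")["y"].mean()
        assert est.group_estimate == pytest.approx(means[1.0] - means[0.0], abs=1e-8)

    def test_noise_free_group_effect_recovered_exactly(self):
        rng = np.random.default_rng(6)
        delta = 2.5
        df = make_panel(
            12, (10, 20, 30), lambda t, w, pid, r: 4.0 + delta * t + 0.1 * w, rng
        )
        est = fit_lmm(df, ModelSpec(outcome="y"))
        assert est.group_estimate == pytest.approx(delta, abs=1e-6)

    def test_mcar_deletion_agrees_with_complete_data(self):
        rng = np.random.default_rng(7)
        b = {}

        def fn(t, w, pid, r):
            if pid not in b:
                b[pid] = r.normal(0, 2.0)
            return 1.0 + 0.8 * t + b[pid] + r.normal(0, 1.0)

        df = make_panel(300, (10, 20, 30), fn, rng)
        est_full = fit_lmm(df, ModelSpec(outcome="y"))
        dfm = df.copy()
        drop = rng.random(len(dfm)) < 0.2
        dfm.loc[drop, "y"] = np.nan
        est_miss = fit_lmm(dfm, ModelSpec(outcome="y"))
        se = est_full.group_se
        assert abs(est_full.group_estimate - est_miss.group_estimate) < 3 * se

    def test_baseline_covariate_included(self):
        rng = np.random.default_rng(8)
        df = make_panel(25, (10, 20), lambda t, w, pid, r: t + r.normal(), rng)
        df["baseline"] = rng.normal(40, 10, size=len(df))
        est = fit_lmm(
            df, ModelSpec(outcome="y", baseline_covariate="baseline")
        )
        assert "baseline" in est.params.index

    def test_no_random_intercept_is_ols(self):
        rng = np.random.default_rng(9)
        df = make_panel(20, (10,), lambda t, w, pid, r: t + r.normal(), rng)
        est = fit_lmm(df, ModelSpec(outcome="y", random_intercept=False))
        assert "ordinary least squares" in est.notes[0]

    def test_ci_is_estimate_pm_196_se(self):
        rng = np.random.default_rng(10)
        df = make_panel(20, (10, 20), lambda t, w, pid, r: t + r.normal(), rng)
        est = fit_lmm(df, ModelSpec(outcome="y"))
        lo, hi = est.group_ci()
        assert lo == pytest.approx(est.group_estimate - 1.96 * est.group_se, abs=1e-4)
        assert hi == pytest.approx(est.group_estimate + 1.96 * est.group_se, abs=1e-4)


class TestLogistic:
    def test_collapsed_2x2_matches_analytic_log_or(self):
        # 2x2 table: blended 30/50 events, standard 15/50
        rows = []
        for treat, n_event, n in ((1.0, 30, 50), (0.0, 15, 50)):
            for i in range(n):
                rows.append(
                    {
                        "patient_id": len(rows),
                        "treat": treat,
                        "week": 10,
                        "y": float(i < n_event),
                    }
                )
        df = pd.DataFrame(rows)
        est = fit_logistic_mixed(
            df, ModelSpec(outcome="y", family="binomial", random_intercept=False)
        )
        log_or = np.log((30 / 20) / (15 / 35))
        assert est.group_estimate == pytest.approx(log_or, abs=1e-6)
        or_, lo, hi = est.group_or()
        assert or_ == pytest.approx(np.exp(log_or), rel=1e-6)
        assert lo < or_ < hi

    def test_constant_outcome_flags_infinite_se(self):
        rng = np.random.default_rng(11)
        df = make_panel(10, (10, 20), lambda t, w, pid, r: 1.0, rng)
        est = fit_logistic_mixed(
            df, ModelSpec(outcome="y", family="binomial", random_intercept=False)
        )
        assert est.group_estimate == 0.0
        assert np.isinf(est.group_se)
        assert any("no variation" in n for n in est.notes)

    def test_complete_separation_raises(self):
        rng = np.random.default_rng(12)
        df = make_panel(20, (10,), lambda t, w, pid, r: t, rng)  # y == treat
        with pytest.raises(ModelError, match="separation"):
            fit_logistic_mixed(
                df, ModelSpec(outcome="y", family="binomial", random_intercept=False)
            )

    def test_time_odds_ratio_recovery(self):
        # declining episode odds: OR 0.23 per assessment step
        from trialcea.synthetic import GeneratorConfig, generate_trial

        cfg = GeneratorConfig(n_per_arm=(2500, 2500), seed=23)
        data = generate_trial(cfg).query("week > 0").copy()
        data["step"] = data["week"] / 10
        import statsmodels.api as sm

        X = sm.add_constant(
            np.column_stack([data["step"], (data["arm"] == "blended").astype(float)])
        )
        fit = sm.Logit(data["episode"], X).fit(disp=0)
        assert np.exp(fit.params.iloc[1]) == pytest.approx(np.exp(-1.47), abs=0.02)


class TestEstimateCeaEffects:
    def _frame(self, rng, n=40, cost_shift=0.0, effect_shift=0.0):
        rows = []
        pid = 0
        for treat in (1.0, 0.0):
            for _ in range(n):
                pid += 1
                for week in (10, 20, 30):
                    rows.append(
                        {
                            "patient_id": pid,
                            "treat": treat,
                            "week": week,
                            "cost": 1000 + cost_shift * treat + rng.normal(0, 50),
                            "effect": float(
                                rng.random() < 0.3 + effect_shift * treat
                            ),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_arms_give_zero_deltas(self):
        rng = np.random.default_rng(13)
        half = self._frame(rng, n=25)
        blended = half[half["treat"] == 1.0]
        mirrored = blended.copy()
        mirrored["treat"] = 0.0
        mirrored["patient_id"] = mirrored["patient_id"] + 10_000
        df = pd.concat([blended, mirrored], ignore_index=True)
        est = estimate_cea_effects(df, "cost", "effect")
        assert est.delta_cost == pytest.approx(0.0, abs=1e-8)
        assert est.delta_effect == pytest.approx(0.0, abs=1e-8)

    def test_single_time_2x2_risk_difference(self):
        rows = []
        for treat, n_event, n in ((1.0, 28, 40), (0.0, 12, 40)):
            for i in range(n):
                rows.append(
                    {
                        "patient_id": len(rows),
                        "treat": treat,
                        "week": 10,
                        "cost": 100.0,
                        "effect": float(i < n_event),
                    }
                )
        df = pd.DataFrame(rows)
        est = estimate_cea_effects(df, "cost", "effect")
        assert est.delta_effect == pytest.approx(28 / 40 - 12 / 40, abs=1e-8)

    def test_known_shift_recovery(self):
        rng = np.random.default_rng(14)
        df = self._frame(rng, n=400, cost_shift=500.0, effect_shift=0.1)
        est = estimate_cea_effects(df, "cost", "effect")
        assert est.delta_cost == pytest.approx(500.0, abs=3 * est.cost.group_se)
        assert est.delta_effect == pytest.approx(0.1, abs=3 * est.effect.group_se)
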