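"""Estimation machinery: QC, Tobit means, metrics, ML fits, CV, selection."""

import numpy as np
import pandas as pd
import pytest
import sympy

from eqvalue.fitting import (
    FitOptions,
    censored_state_means,
    crossvalidate_blocks,
    fit_metrics,
    fit_model,
    qc_exclude,
    select_model,
)
from eqvalue.models import HybridLikelihood, ModelSpec
from eqvalue.synthetic_data import (
    DEFAULT_TRUTH,
    InterviewDataset,
    TruePreferences,
    simulate_study,
)


def _make_dataset(ctto, respondents=None, dce=None):
    if respondents is None:
        ids = np.unique(ctto["respondent_id"])
        respondents = pd.DataFrame({"id": ids, "duration_min": 15.0})
    if dce is None:
        dce = pd.DataFrame(
            columns=["respondent_id", "block", "state_a", "state_b", "chose_a"]
        )
    return InterviewDataset(ctto=ctto, dce=dce, respondents=respondents)


class TestQualityControl:
    def _toy(self, values_by_resp, durations):
        rows = []
        for rid, vals in values_by_resp.items():
            for code, v in vals.items():
                rows.append({"respondent_id": rid, "block": 0, "state_code": code,
                             "value": v, "flagged": False})
        ctto = pd.DataFrame(rows)
        resp = pd.DataFrame(
            {"id": list(values_by_resp), "duration_min": durations}
        )
        return _make_dataset(ctto, resp)

    def test_fast_interview_excluded(self):
        ds = self._toy(
            {0: {"21111": 0.9, "55555": -0.8}, 1: {"21111": 0.95, "55555": -0.7}},
            durations=[4.9, 12.0],
        )
        clean, report = qc_exclude(ds)
        assert report["excluded_ids"] == [0]
        assert set(clean.respondents["id"]) == {1}

    def test_worst_state_violation_excludes_exactly_that_respondent(self):
        ds = self._toy(
            {
                0: {"21111": 0.9, "33333": 0.4, "55555": -0.6},
                1: {"21111": 0.95, "33333": 0.3, "55555": 0.9},   # 0.5 above minimum
                2: {"21111": 0.85, "33333": 0.2, "55555": -0.9},
            },
            durations=[10.0, 10.0, 10.0],
        )
        clean, report = qc_exclude(ds)
        assert report["excluded_ids"] == [1]
        assert report["n_excluded_worst_state_rule"] == 1
        assert set(clean.respondents["id"]) == {0, 2}

    def test_feedback_flagged_rows_removed_but_respondent_kept(self):
        ds = self._toy({0: {"21111": 0.9, "55555": -0.8}}, durations=[10.0])
        ds.ctto.loc[0, "flagged"] = True
        clean, report = qc_exclude(ds)
        assert report["n_flagged_rows_removed"] == 1
        assert len(clean.ctto) == 1
        assert set(clean.respondents["id"]) == {0}

    def test_missing_duration_column_raises(self):
        ds = self._toy({0: {"55555": -1.0, "21111": 0.9}}, durations=[10.0])
        ds.respondents = ds.respondents.drop(columns="duration_min")
        with pytest.raises(ValueError, match="duration"):
            qc_exclude(ds)


class TestCensoredStateMeans:
    def test_uncensored_state_reduces_to_weighted_mean(self):
        ctto = pd.DataFrame(
            {
                "respondent_id": [0, 1, 2, 0, 1],
                "block": 0,
                "state_code": ["22222"] * 3 + ["33333"] * 2,
                "value": [0.6, 0.8, 0.7, 0.3, 0.5],
                "flagged": False,
            }
        )
        w = {0: 2.0, 1: 1.0, 2: 1.0}
        csm = censored_state_means(ctto, weights=w)
        expect_22222 = np.average([0.6, 0.8, 0.7], weights=[2, 1, 1])
        assert csm.table.at["22222", "mean_value"] == pytest.approx(expect_22222, abs=1e-5)
        assert not csm.table["all_censored"].any()

    def test_all_censored_state_flagged_at_floor(self):
        ctto = pd.DataFrame(
            {
                "respondent_id": [0, 1, 0, 1],
                "block": 0,
                "state_code": ["55555", "55555", "22222", "22222"],
                "value": [-1.0, -1.0, 0.6, 0.7],
                "flagged": False,
            }
        )
        with pytest.warns(UserWarning, match="censored"):
            csm = censored_state_means(ctto)
        assert bool(csm.table.at["55555", "all_censored"]) is True
        assert csm.table.at["55555", "mean_value"] == -1.0

    def test_censoring_pulls_mean_below_naive_average(self, toy_ctto):
        csm = censored_state_means(toy_ctto)
        naive = toy_ctto.loc[toy_ctto["state_code"] == "55555", "value"].mean()
        assert csm.table.at["55555", "mean_value"] < naive


class TestFitMetrics:
    def test_perfect_agreement(self):
        x = np.array([0.1, 0.4, -0.2, 0.9, 0.0])
        m = fit_metrics(x, x)
        assert m["RMSE"] == 0 and m["MAE"] == 0
        assert m["LinCCC"] == pytest.approx(1.0)
        assert m["PearsonR"] == pytest.approx(1.0)

    def test_constant_shift(self):
        ref = np.array([0.1, 0.4, -0.2, 0.9, 0.0])
        m = fit_metrics(ref + 0.05, ref)
        assert m["RMSE"] == pytest.approx(0.05, abs=1e-12)
        assert m["MAE"] == pytest.approx(0.05, abs=1e-12)
        assert m["PearsonR"] == pytest.approx(1.0)
        assert m["LinCCC"] < 1.0

    def test_five_point_symbolic_oracle(self):
        xs = [sympy.Rational(r) for r in ("1/10", "2/10", "4/10", "7/10", "9/10")]
        ys = [sympy.Rational(r) for r in ("15/100", "18/100", "45/100", "66/100", "95/100")]
        n = 5
        mx, my = sum(xs) / n, sum(ys) / n
        sxx = sum((x - mx) ** 2 for x in xs) / n
        syy = sum((y - my) ** 2 for y in ys) / n
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
        rmse = sympy.sqrt(sum((x - y) ** 2 for x, y in zip(xs, ys)) / n)
        mae = sum(abs(x - y) for x, y in zip(xs, ys)) / n
        ccc = 2 * sxy / (sxx + syy + (mx - my) ** 2)
        pearson = sxy / sympy.sqrt(sxx * syy)
        m = fit_metrics(np.array([float(x) for x in xs]), np.array([float(y) for y in ys]))
        assert m["RMSE"] == pytest.approx(float(rmse), abs=1e-12)
        assert m["MAE"] == pytest.approx(float(mae), abs=1e-12)
        assert m["LinCCC"] == pytest.approx(float(ccc), abs=1e-12)
        assert m["PearsonR"] == pytest.approx(float(pearson), abs=1e-12)

    def test_invariances(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(size=40)
        m = fit_metrics(x, y)
        perm = rng.permutation(40)
        mp = fit_metrics(x[perm], y[perm])
        assert mp["PearsonR"] == pytest.approx(m["PearsonR"], abs=1e-12)
        assert mp["LinCCC"] == pytest.approx(m["LinCCC"], abs=1e-12)
        mf = fit_metrics(-x, -y)
        assert mf["RMSE"] == pytest.approx(m["RMSE"], abs=1e-12)
        assert mf["MAE"] == pytest.approx(m["MAE"], abs=1e-12)

    def test_icc_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.3, size=30) + 0.1
        long = pd.DataFrame(
            {
                "target": np.r_[np.arange(30), np.arange(30)],
                "rater": ["a"] * 30 + ["b"] * 30,
                "score": np.r_[x, y],
            }
        )
        icc = pingouin.intraclass_corr(long, targets="target", raters="rater", ratings="score")
        ref = float(icc.loc[icc["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert fit_metrics(x, y)["ICC"] == pytest.approx(ref, abs=1e-8)


class TestFitModel:
    def test_refit_from_optimum_is_fixed_point(self, small_study, fast_options):
        spec = ModelSpec()
        fit1 = fit_model(spec, small_study, options=fast_options, compute_metrics=False)
        fit2 = fit_model(
            spec, small_study, options=fast_options,
            x0=fit1.params.pack(spec), compute_metrics=False,
        )
        assert abs(fit1.loglik - fit2.loglik) < 1e-8
        assert fit1.loglik >= fit1.start_loglik  # optimizer never went downhill

    def test_wls_closed_form_in_degenerate_case(self, small_study):
        spec = ModelSpec(
            form="additive20", intercept=True, data="ctto_only",
            heteroscedastic=False, random_intercept=False, censored=False,
        )
        rng = np.random.default_rng(2)
        ids = small_study.respondents["id"].to_numpy()
        w = pd.Series(rng.uniform(0.5, 2.0, size=len(ids)), index=ids)
        fit = fit_model(
            spec, small_study, weights=w,
            options=FitOptions(n_starts=1, gtol=1e-9), compute_metrics=False,
        )
        df = small_study.ctto
        levels = np.array([[int(c) for c in s] for s in df["state_code"]])
        X = np.zeros((len(df), 21))
        X[:, 0] = 1.0
        for d in range(5):
            for l in (2, 3, 4, 5):
                X[levels[:, d] == l, 1 + d * 4 + l - 2] = 1.0
        y = 1.0 - df["value"].to_numpy()
        wr = w.reindex(df["respondent_id"]).to_numpy()
        beta_wls = np.linalg.solve(X.T @ (X * wr[:, None]), X.T @ (wr * y))
        got = fit.params.pack(spec)
        np.testing.assert_allclose(got[:20], beta_wls[1:], atol=1e-6)
        assert got[20] == pytest.approx(beta_wls[0], abs=1e-6)

    def test_nonconvergence_is_reported_not_silent(self, small_study):
        spec = ModelSpec()
        with pytest.warns(UserWarning, match="converge"):
            fit = fit_model(
                spec, small_study,
                options=FitOptions(n_starts=1, n_quad=9, maxiter=2),
                compute_metrics=False,
            )
        assert not fit.converged


class TestCrossValidation:
    def test_low_noise_cv_rmse_at_grid_floor(self):
        truth = TruePreferences(DEFAULT_TRUTH.coeffs, tau=0.01, sigma_a=0.02, sigma_b=0.0)
        ds = simulate_study(truth, n_respondents=150, seed=21)
        cv = crossvalidate_blocks(
            ModelSpec(), ds, options=FitOptions(n_starts=1, n_quad=9)
        )
        assert cv["rmse"] < 0.02

    def test_folds_deterministic(self, small_study, fast_options):
        a = crossvalidate_blocks(ModelSpec(), small_study, options=fast_options)
        b = crossvalidate_blocks(ModelSpec(), small_study, options=fast_options)
        assert a["rmse"] == b["rmse"]
        assert len(a["folds"]) == 10

    def test_correct_model_beats_frozen_level_misspecification(self):
        # misspecified baseline: level multipliers frozen at equal spacing
        wins = 0
        for rep in range(3):
            ds = simulate_study(n_respondents=400, seed=500 + rep)
            opts = FitOptions(n_starts=1, n_quad=9)
            cv_correct = crossvalidate_blocks(ModelSpec(), ds, options=opts)
            cv_wrong = _crossvalidate_frozen_levels(ds, np.array([0.25, 0.5, 0.75]), opts)
            wins += cv_correct["rmse"] < cv_wrong
        assert wins >= 2


def _fit_frozen_levels(dataset, L_fix, opts, x0=None):
    spec = ModelSpec()
    eng = HybridLikelihood(dataset, spec, n_quad=opts.n_quad)
    keep = np.r_[np.arange(5), np.arange(8, 12)]  # betas + nuisance, L frozen

    def to_full(xf):
        return np.concatenate([xf[:5], L_fix, xf[5:]])

    from scipy.optimize import minimize

    def fun(xf):
        ll, g = eng.loglik_and_grad(to_full(xf))
        if not np.isfinite(ll):
            return 1e10, np.zeros_like(xf)
        return -ll / eng.total_weight, -g[keep] / eng.total_weight

    if x0 is None:
        from eqvalue.fitting import starting_values

        x0 = starting_values(spec, dataset)[keep]
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", options={"gtol": 1e-5, "maxiter": 500})
    return res.x


def _crossvalidate_frozen_levels(dataset, L_fix, opts):
    csm = censored_state_means(dataset.ctto)
    warm = _fit_frozen_levels(dataset, L_fix, opts)
    L = np.array([0.0, *L_fix, 1.0])
    errors = []
    for block in sorted(dataset.ctto["block"].unique()):
        held = dataset.ctto["block"] == block
        train = InterviewDataset(
            dataset.ctto[~held].reset_index(drop=True), dataset.dce, dataset.respondents
        )
        x = _fit_frozen_levels(train, L_fix, opts, x0=warm)
        codes = sorted(set(dataset.ctto.loc[held, "state_code"]))
        codes = [c for c in codes if not csm.table.at[c, "all_censored"]]
        levels = np.array([[int(ch) for ch in c] for c in codes])
        pred = 1.0 - (L[levels - 1] * x[:5]).sum(axis=1)
        errors.append(pred - csm.values_for(codes))
    err = np.concatenate(errors)
    return float(np.sqrt(np.mean(err**2)))


class TestSelectModel:
    def test_inconsistent_candidate_never_selected(self, small_study, fast_options, monkeypatch):
        import eqvalue.fitting as fitting_mod

        candidates = [ModelSpec(), ModelSpec(intercept=True)]
        baseline = select_model(candidates, small_study, options=fast_options)
        best = baseline["selected_spec"].label()
        other = next(s.label() for s in candidates if s.label() != best)

        real = fitting_mod.is_consistent

        def veto_best(coeffs):
            report = real(coeffs)
            # declare the otherwise-winning fit inconsistent
            if report["consistent"] and veto_best.counter[0] < len(candidates):
                veto_best.counter[0] += 1
            return report

        veto_best.counter = [0]

        def fake(coeffs):
            return {"consistent": False, "violations": [("fake", "fake")]}

        # make the previously selected spec's fit report inconsistent
        orig_fit = fitting_mod.fit_model

        def patched_fit(spec, *a, **kw):
            result = orig_fit(spec, *a, **kw)
            if spec.label() == best and kw.get("compute_metrics", True):
                result.consistency = fake(result.params.coeffs)
            return result

        monkeypatch.setattr(fitting_mod, "fit_model", patched_fit)
        forced = select_model(candidates, small_study, options=fast_options)
        assert forced["selected_spec"].label() == other

    def test_all_consistent_picks_min_cv_rmse(self, small_study, fast_options):
        candidates = [ModelSpec(), ModelSpec(intercept=True)]
        sel = select_model(candidates, small_study, options=fast_options)
        rmses = {label: cv["rmse"] for label, cv in sel["cv"].items()}
        assert sel["selected_spec"].label() == min(rmses, key=rmses.get)
        assert set(sel["comparison"].columns) == {s.label() for s in candidates}
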