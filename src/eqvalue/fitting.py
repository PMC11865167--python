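"""Model estimation: QC exclusions, maximum likelihood, Tobit censored state
means, fit metrics, leave-one-block-out cross-validation and model selection.

Estimation maximises the (weighted) hybrid log-likelihood by quasi-Newton
(L-BFGS-B) with analytic gradients, from a deterministic start: OLS of the
uncensored disutilities on the 20 dimension-level dummies (collapsed to the
multiplicative form when needed), tau = 0.1, sigma from the OLS residual SD,
theta = 3.  Optional multi-start (default 3 seeded perturbed starts) guards
against local optima.  The optimizer works on the objective normalised by the
total respondent weight, so the convergence criterion (projected gradient
below ``gtol``) is sample-size invariant.

The reference for all fit metrics and for cross-validation is the set of
Tobit censored state means: one mean per directly valued state with a shared
residual SD, right-censored at disutility 2, reported on the value scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.stats import pearsonr

from .models import (
    HybridLikelihood,
    ModelSpec,
    ParameterVector,
    _resolve_weights,
)
from .state_space import is_consistent
from .synthetic_data import InterviewDataset

__all__ = [
    "FitOptions",
    "FitResult",
    "CensoredStateMeans",
    "qc_exclude",
    "censored_state_means",
    "starting_values",
    "fit_model",
    "fit_metrics",
    "crossvalidate_blocks",
    "select_model",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# -- quality control ---------------------------------------------------------


def qc_exclude(
    dataset: InterviewDataset,
    time_rule: bool = True,
    min_minutes: float = 5.0,
    worst_gap_rule: bool = True,
    worst_gap: float = 0.5,
    worst_not_lowest_rule: bool = True,
) -> tuple[InterviewDataset, dict]:
    """Apply the protocol-compliance exclusions.

    * feedback-flagged cTTO rows are removed;
    * respondents spending less than ``min_minutes`` on the ten cTTO tasks
      are excluded entirely (cTTO and DCE);
    * respondents whose 55555 valuation is at least ``worst_gap`` above their
      lowest other valuation, or strictly above their highest other valuation,
      are excluded entirely.  Each 55555 sub-rule is switchable.
    """
    ctto = dataset.ctto
    flagged = ctto["flagged"].fillna(False).astype(bool)
    n_flagged = int(flagged.sum())
    ctto = ctto[~flagged]

    excluded: dict[str, list] = {"fast_interview": [], "worst_state_rule": []}
    if time_rule:
        if "duration_min" not in dataset.respondents.columns:
            raise ValueError("time rule enabled but respondents have no duration_min column")
        fast = dataset.respondents.loc[
            dataset.respondents["duration_min"] < min_minutes, "id"
        ].tolist()
        excluded["fast_interview"] = fast

    if worst_gap_rule or worst_not_lowest_rule:
        for rid, g in ctto.groupby("respondent_id"):
            worst = g.loc[g["state_code"] == "55555", "value"]
            others = g.loc[g["state_code"] != "55555", "value"]
            if len(worst) == 0 or len(others) == 0:
                continue
            v55 = float(worst.iloc[0])
            hit = worst_gap_rule and v55 >= float(others.min()) + worst_gap
            hit = hit or (worst_not_lowest_rule and v55 > float(others.max()))
            if hit:
                excluded["worst_state_rule"].append(rid)

    drop = set(excluded["fast_interview"]) | set(excluded["worst_state_rule"])
    keep_ids = [i for i in dataset.respondents["id"] if i not in drop]
    clean = InterviewDataset(
        ctto=ctto[ctto["respondent_id"].isin(keep_ids)].reset_index(drop=True),
        dce=dataset.dce[dataset.dce["respondent_id"].isin(keep_ids)].reset_index(drop=True),
        respondents=dataset.respondents[dataset.respondents["id"].isin(keep_ids)].reset_index(
            drop=True
        ),
    )
    report = {
        "n_flagged_rows_removed": n_flagged,
        "n_excluded_fast_interview": len(excluded["fast_interview"]),
        "n_excluded_worst_state_rule": len(set(excluded["worst_state_rule"])),
        "n_excluded_total": len(drop),
        "excluded_ids": sorted(drop),
    }
    return clean, report


# -- Tobit censored state means ---------------------------------------------


@dataclass
class CensoredStateMeans:
    """Per-state censored-ML mean values with a shared residual SD.

    ``table``: index state_code, columns mean_value, mean_disutility, n_obs,
    n_censored, all_censored.  States whose observations are all censored are
    reported at the response floor (value -1) and flagged.
    """

    table: pd.DataFrame
    sigma: float
    converged: bool

    def values_for(self, codes) -> np.ndarray:
        return self.table.loc[list(codes), "mean_value"].to_numpy()


def censored_state_means(ctto_data: pd.DataFrame, weights=None) -> CensoredStateMeans:
    """Joint Tobit: one mean per directly valued state, shared sigma.

    Maximum likelihood with right-censoring at disutility 2 (observed value
    -1); observation weights are the respondent weights.
    """
    df = ctto_data
    resp_ids = np.unique(df["respondent_id"].to_numpy())
    w_resp = _resolve_weights(weights, resp_ids)
    w_of = dict(zip(resp_ids, w_resp))
    w_row = df["respondent_id"].map(w_of).to_numpy(dtype=float)

    codes, state_idx = np.unique(df["state_code"].to_numpy(), return_inverse=True)
    du = 1.0 - df["value"].to_numpy(dtype=float)
    cens = df["value"].to_numpy(dtype=float) <= -1.0 + 1e-9

    n_obs_state = np.bincount(state_idx, minlength=len(codes))
    n_cens_state = np.bincount(state_idx, weights=cens.astype(float), minlength=len(codes))
    all_cens = n_cens_state >= n_obs_state

    est = np.zeros(len(codes))  # fitted means on the disutility scale
    free = ~all_cens
    free_idx = {j: k for k, j in enumerate(np.where(free)[0])}
    sub = free[state_idx]
    s_idx = np.array([free_idx[j] for j in state_idx[sub]])
    du_s, cens_s, w_s = du[sub], cens[sub], w_row[sub]
    n_free = int(free.sum())

    def nll_grad(x):
        mu = x[:n_free][s_idx]
        sigma = np.exp(x[-1])
        ll = 0.0
        gmu = np.zeros(n_free)
        u = ~cens_s
        z = (du_s[u] - mu[u]) / sigma
        ll += np.sum(w_s[u] * (-0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma)))
        np.add.at(gmu, s_idx[u], w_s[u] * z / sigma)
        g_lsig = np.sum(w_s[u] * (z * z - 1.0))
        if cens_s.any():
            c = (2.0 - mu[cens_s]) / sigma
            ll += np.sum(w_s[cens_s] * log_ndtr(-c))
            h = np.exp(-0.5 * c * c - _LOG_SQRT_2PI - log_ndtr(-c))
            np.add.at(gmu, s_idx[cens_s], w_s[cens_s] * h / sigma)
            g_lsig += np.sum(w_s[cens_s] * h * c)
        return -ll, -np.concatenate([gmu, [g_lsig]])

    # start: weighted sample means (censored rows at the bound), pooled SD
    mu0 = np.zeros(n_free)
    for j in np.where(free)[0]:
        rows = state_idx == j
        mu0[free_idx[j]] = np.average(du[rows], weights=w_row[rows])
    x0 = np.concatenate([mu0, [np.log(max(np.std(du), 0.05))]])
    res = minimize(nll_grad, x0, jac=True, method="L-BFGS-B", options={"maxiter": 2000})
    est[free] = res.x[:n_free]
    est[all_cens] = 2.0
    if all_cens.any():
        warnings.warn(
            f"{int(all_cens.sum())} state(s) have all observations censored; "
            "means reported at the response floor",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "mean_value": 1.0 - est,
            "mean_disutility": est,
            "n_obs": n_obs_state,
            "n_censored": n_cens_state.astype(int),
            "all_censored": all_cens,
        },
        index=pd.Index(codes, name="state_code"),
    )
    return CensoredStateMeans(table, sigma=float(np.exp(res.x[-1])), converged=bool(res.success))


# -- fit metrics -------------------------------------------------------------


def _lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.var(), y.var()
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * sxy / (sx + sy + (x.mean() - y.mean()) ** 2))


def _icc_a1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(A,1): two-way, absolute agreement, single measure, k = 2 raters."""
    n, k = len(x), 2
    data = np.column_stack([x, y])
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    grand = data.mean()
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def fit_metrics(predicted: np.ndarray, reference: np.ndarray) -> dict:
    """Agreement between predicted values and censored state means.

    Computed over the directly valued states only (the caller aligns the two
    vectors).  Lin's CCC uses biased (1/n) variances; ICC is the two-way
    absolute-agreement single-measure coefficient.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference must be aligned")
    err = predicted - reference
    return {
        "RMSE": float(np.sqrt(np.mean(err**2))),
        "MAE": float(np.mean(np.abs(err))),
        "LinCCC": _lin_ccc(predicted, reference),
        "ICC": _icc_a1(predicted, reference),
        "PearsonR": float(pearsonr(predicted, reference)[0]),
    }


# -- maximum likelihood ------------------------------------------------------


@dataclass
class FitOptions:
    n_quad: int = 31
    n_starts: int = 3
    seed: int = 0
    gtol: float = 1e-5
    maxiter: int = 1000
    perturb_sd: float = 0.05


@dataclass
class FitResult:
    spec: ModelSpec
    params: ParameterVector
    loglik: float
    converged: bool
    n_iter: int
    start_loglik: float
    metrics: dict = field(default_factory=dict)
    consistency: dict = field(default_factory=dict)
    optimizer_message: str = ""

    def coefficient_series(self) -> pd.Series:
        return self.params.as_series(self.spec)

    def predicted_values(self, codes) -> np.ndarray:
        levels = np.array([[int(c) for c in code] for code in codes])
        return 1.0 - self.params.coeffs.disutility_of_levels(levels)


def starting_values(spec: ModelSpec, dataset: InterviewDataset) -> np.ndarray:
    """Deterministic start: dummy-OLS on uncensored disutilities."""
    df = dataset.ctto
    unc = df["value"].to_numpy(dtype=float) > -1.0 + 1e-9
    sub = df[unc] if unc.any() else df
    levels = np.array([[int(c) for c in code] for code in sub["state_code"]])
    X = np.zeros((len(sub), 20))
    for d in range(5):
        for l in (2, 3, 4, 5):
            X[levels[:, d] == l, d * 4 + (l - 2)] = 1.0
    du = 1.0 - sub["value"].to_numpy(dtype=float)
    Xd = np.column_stack([np.ones(len(sub)), X])
    coef, *_ = np.linalg.lstsq(Xd, du, rcond=None)
    resid_sd = float(np.std(du - Xd @ coef))
    b20 = coef[1:].reshape(5, 4)  # rows: dimensions, cols: levels 2..5

    x: list[float] = []
    if spec.form == "multiplicative8":
        b5 = np.maximum(b20[:, 3], 0.05)  # level-5 dummies anchor beta_d
        with np.errstate(invalid="ignore"):
            ratios = b20[:, :3] / b5[:, None]
        L = np.clip(np.nanmean(ratios, axis=0), 0.02, 0.98)
        L = np.sort(L)
        x += list(b5) + list(L)
    else:
        x += list(np.maximum(b20, 0.01).ravel())
    if spec.intercept:
        x.append(max(coef[0], 0.0))
    if spec.random_intercept:
        # tau start 0.1, shrunk at very low residual noise: far above the
        # residual scale the non-adaptive quadrature plateaus and the
        # gradient vanishes, stranding the optimizer
        x.append(np.log(min(0.1, max(0.5 * resid_sd, 1e-3))))
    if spec.heteroscedastic:
        x += [max(resid_sd, 0.05), 0.0]
    else:
        x.append(max(resid_sd, 0.05))
    if spec.data == "hybrid":
        x.append(np.log(3.0))
    return np.array(x)


def _maximize(engine, x0: np.ndarray, options: FitOptions):
    scale = engine.total_weight

    def fun(x):
        ll, g = engine.loglik_and_grad(x)
        if not np.isfinite(ll):
            return 1e10, np.zeros_like(x)
        return -ll / scale, -g / scale

    return minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": options.maxiter, "gtol": options.gtol, "ftol": 1e-12},
    )


def fit_model(
    spec: ModelSpec,
    dataset: InterviewDataset,
    weights=None,
    options: FitOptions | None = None,
    x0: np.ndarray | None = None,
    reference: CensoredStateMeans | None = None,
    compute_metrics: bool = True,
) -> FitResult:
    """Maximise the (hybrid) likelihood for one model variant.

    ``x0`` overrides the deterministic start (used for warm starts in
    cross-validation and the bootstrap).  Fit metrics are computed against
    ``reference`` censored state means (computed from the full cTTO data when
    not supplied).
    """
    options = options or FitOptions()
    engine = HybridLikelihood(dataset, spec, weights, options.n_quad)
    starts = [x0 if x0 is not None else starting_values(spec, dataset)]
    rng = np.random.default_rng(options.seed)
    for _ in range(options.n_starts - 1):
        starts.append(starts[0] + rng.normal(0.0, options.perturb_sd, size=len(starts[0])))

    best = None
    start_ll = engine.loglik_and_grad(starts[0])[0]
    for s in starts:
        res = _maximize(engine, s, options)
        if best is None or -res.fun > -best.fun:
            best = res
    assert best is not None
    ll = -best.fun * engine.total_weight
    grad_norm = float(np.max(np.abs(best.jac)))
    converged = bool(best.success) and grad_norm < max(options.gtol * 10, 1e-4)
    params = ParameterVector.unpack(best.x, spec)
    if not converged:
        warnings.warn(
            f"fit for {spec.label()} did not converge: {best.message} "
            f"(projected gradient {grad_norm:.2e})",
            stacklevel=2,
        )

    result = FitResult(
        spec=spec,
        params=params,
        loglik=float(ll),
        converged=converged,
        n_iter=int(best.nit),
        start_loglik=float(start_ll),
        optimizer_message=str(best.message),
    )
    if compute_metrics:
        if reference is None:
            reference = censored_state_means(dataset.ctto, weights)
        ok = ~reference.table["all_censored"].to_numpy()
        codes = reference.table.index.to_numpy()[ok]
        result.metrics = fit_metrics(result.predicted_values(codes), reference.values_for(codes))
    result.consistency = is_consistent(params.coeffs)
    return result


# -- cross-validation and selection -----------------------------------------


def crossvalidate_blocks(
    spec: ModelSpec,
    dataset: InterviewDataset,
    weights=None,
    options: FitOptions | None = None,
    reference: CensoredStateMeans | None = None,
    base_fit: FitResult | None = None,
) -> dict:
    """Leave-one-cTTO-block-out out-of-sample RMSE.

    Each of the 10 blocks is held out in turn; the model is refitted on the
    other 9 (warm-started from the full-data optimum; DCE data always
    included for hybrid variants) and the held-out block's states are
    predicted and compared against censored state means computed from the
    full data.  The pooled RMSE over all held-out (block, state) predictions
    is returned.
    """
    options = options or FitOptions()
    if reference is None:
        reference = censored_state_means(dataset.ctto, weights)
    if base_fit is None:
        base_fit = fit_model(spec, dataset, weights, options, reference=reference)
    warm = base_fit.params.pack(spec)
    fold_opts = FitOptions(**{**options.__dict__, "n_starts": 1})

    errors: list[np.ndarray] = []
    folds = []
    for block in sorted(dataset.ctto["block"].unique()):
        held = dataset.ctto["block"] == block
        train = InterviewDataset(
            ctto=dataset.ctto[~held].reset_index(drop=True),
            dce=dataset.dce,
            respondents=dataset.respondents,
        )
        held_codes = sorted(set(dataset.ctto.loc[held, "state_code"]))
        held_codes = [
            c for c in held_codes if c in reference.table.index and not reference.table.at[c, "all_censored"]
        ]
        try:
            fit = fit_model(
                spec, train, weights, fold_opts, x0=warm, compute_metrics=False
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"fold for block {block} skipped: {exc}", stacklevel=2)
            folds.append({"block": int(block), "skipped": True, "reason": str(exc)})
            continue
        err = fit.predicted_values(held_codes) - reference.values_for(held_codes)
        errors.append(err)
        folds.append({"block": int(block), "skipped": False, "rmse": float(np.sqrt(np.mean(err**2)))})
    if not errors:
        raise RuntimeError("all cross-validation folds failed")
    all_err = np.concatenate(errors)
    return {"rmse": float(np.sqrt(np.mean(all_err**2))), "n_predictions": len(all_err), "folds": folds}


def select_model(
    candidates: list[ModelSpec],
    dataset: InterviewDataset,
    weights=None,
    options: FitOptions | None = None,
) -> dict:
    """Fit all candidate variants, discard logically inconsistent ones, and
    select the minimum out-of-sample RMSE among the rest.

    Returns ``{"selected": FitResult, "selected_spec": ModelSpec,
    "comparison": DataFrame, "cv": {label: cv_result}}``; the comparison
    table mirrors the published layout (coefficients then fit metrics, one
    column per candidate).
    """
    options = options or FitOptions()
    reference = censored_state_means(dataset.ctto, weights)
    fits: dict[str, FitResult] = {}
    cv: dict[str, dict] = {}
    rows: dict[str, pd.Series] = {}
    for spec in candidates:
        fit = fit_model(spec, dataset, weights, options, reference=reference)
        fits[spec.label()] = fit
        cv[spec.label()] = crossvalidate_blocks(
            spec, dataset, weights, options, reference=reference, base_fit=fit
        )
        col = fit.coefficient_series()
        for name, value in fit.metrics.items():
            col[name] = value
        col["CV_RMSE"] = cv[spec.label()]["rmse"]
        col["consistent"] = fit.consistency["consistent"]
        col["converged"] = fit.converged
        rows[spec.label()] = col
    comparison = pd.DataFrame(rows)

    eligible = [
        (label, cv[label]["rmse"])
        for label, fit in fits.items()
        if fit.consistency["consistent"] and fit.converged
    ]
    if not eligible:
        raise RuntimeError("no logically consistent converged candidate model")
    selected_label = min(eligible, key=lambda t: t[1])[0]
    selected_spec = next(s for s in candidates if s.label() == selected_label)
    return {
        "selected": fits[selected_label],
        "selected_spec": selected_spec,
        "comparison": comparison,
        "cv": cv,
        "fits": fits,
    }
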