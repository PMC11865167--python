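"""Respondent-level bootstrap for coefficient and value-set uncertainty.

Respondents are resampled with replacement, each carrying their full cTTO and
DCE records; when a weighting procedure is supplied the weights are re-derived
inside every replicate so that weight uncertainty propagates.  Replicate fits
are warm-started from the full-data optimum.  Standard errors are the SD of
replicate estimates; 95% confidence intervals are the 2.5/97.5 percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitOptions, FitResult, fit_model
from .models import ModelSpec
from .state_space import enumerate_states
from .synthetic_data import InterviewDataset

__all__ = ["BootstrapResult", "bootstrap"]


@dataclass
class BootstrapResult:
    """coefficients: index parameter, columns estimate/se/ci_low/ci_high;
    values: index state_code, columns utility/se/ci_low/ci_high."""

    coefficients: pd.DataFrame
    values: pd.DataFrame
    n_requested: int
    n_converged: int
    replicate_coefficients: pd.DataFrame


def _take_rows(df: pd.DataFrame, draw: np.ndarray, id_col: str) -> pd.DataFrame:
    """Rows of df for each drawn respondent, relabelled 0..n-1 in draw order."""
    df = df.reset_index(drop=True)
    positions = dict(df.groupby(id_col).indices)
    rows, new_ids = [], []
    for k, rid in enumerate(draw):
        pos = positions.get(rid)
        if pos is None:
            continue
        rows.append(pos)
        new_ids.append(np.full(len(pos), k))
    if not rows:
        return df.iloc[:0]
    out = df.iloc[np.concatenate(rows)].copy()
    out[id_col] = np.concatenate(new_ids)
    return out.reset_index(drop=True)


def _resample(dataset: InterviewDataset, rng: np.random.Generator) -> InterviewDataset:
    ids = dataset.respondents["id"].to_numpy()
    draw = rng.choice(ids, size=len(ids), replace=True)
    return InterviewDataset(
        ctto=_take_rows(dataset.ctto, draw, "respondent_id"),
        dce=_take_rows(dataset.dce, draw, "respondent_id"),
        respondents=_take_rows(dataset.respondents, draw, "id"),
    )


def bootstrap(
    spec: ModelSpec,
    dataset: InterviewDataset,
    B: int,
    seed: int,
    weights_procedure=None,
    options: FitOptions | None = None,
    base_fit: FitResult | None = None,
    max_nonconverged_frac: float = 0.05,
) -> BootstrapResult:
    """Bootstrap SEs and percentile 95% CIs for coefficients and all 3,125
    state values.

    ``weights_procedure`` is an optional callable mapping a respondents
    DataFrame to a weight Series (e.g. a closure over population margins);
    it is re-run inside each replicate.  More than ``max_nonconverged_frac``
    dropped replicates raises.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    options = options or FitOptions()
    weights = (
        weights_procedure(dataset.respondents) if weights_procedure is not None else None
    )
    if base_fit is None:
        base_fit = fit_model(spec, dataset, weights, options)
    warm = base_fit.params.pack(spec)
    rep_opts = FitOptions(**{**options.__dict__, "n_starts": 1})

    rng = np.random.default_rng(seed)
    codes = [s.code for s in enumerate_states()]
    coef_rows, value_rows = [], []
    n_dropped = 0
    for b in range(B):
        rep = _resample(dataset, rng)
        w = weights_procedure(rep.respondents) if weights_procedure is not None else None
        if isinstance(w, pd.Series):
            w = pd.Series(w.to_numpy(), index=rep.respondents["id"].to_numpy())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_model(spec, rep, w, rep_opts, x0=warm, compute_metrics=False)
        except Exception:
            n_dropped += 1
            continue
        if not fit.converged:
            n_dropped += 1
            continue
        coef_rows.append(fit.coefficient_series())
        value_rows.append(fit.predicted_values(codes))
    if n_dropped > max_nonconverged_frac * B:
        raise RuntimeError(f"{n_dropped}/{B} bootstrap replicates failed to converge")

    coefs = pd.DataFrame(coef_rows).reset_index(drop=True)
    vals = np.array(value_rows)
    point = base_fit.coefficient_series()
    coefficients = pd.DataFrame(
        {
            "estimate": point,
            "se": coefs.std(ddof=1),
            "ci_low": coefs.quantile(0.025),
            "ci_high": coefs.quantile(0.975),
        }
    )
    point_values = base_fit.predicted_values(codes)
    values = pd.DataFrame(
        {
            "utility": point_values,
            "se": vals.std(axis=0, ddof=1),
            "ci_low": np.quantile(vals, 0.025, axis=0),
            "ci_high": np.quantile(vals, 0.975, axis=0),
        },
        index=pd.Index(codes, name="state_code"),
    )
    return BootstrapResult(
        coefficients=coefficients,
        values=values,
        n_requested=B,
        n_converged=B - n_dropped,
        replicate_coefficients=coefs,
    )
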