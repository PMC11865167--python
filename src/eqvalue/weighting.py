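"""Re-weighting the respondent sample to general-population margins.

Only marginal population totals (age group, sex, education, region) are
available, so the default procedure is iterative proportional fitting
(raking): weights start at 1 and are multiplicatively adjusted one
characteristic at a time until every weighted sample margin matches its
population target.  Weights are normalised to mean 1 and optionally trimmed.

A logistic-propensity variant is provided behind ``method="logistic"``: a
pseudo-population is expanded from the margins under independence, a logistic
model of sample membership on the characteristic dummies is fitted
(statsmodels), and respondents are weighted by the inverse odds of selection.
With independent margins it coincides with raking up to sampling noise.

Sample categories absent from the margins (e.g. gender "other") keep their
weighted share; the listed targets are rescaled to the remaining mass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_weights", "weighted_refit_delta", "read_margins", "write_margins"]


def _weighted_shares(values: pd.Series, w: np.ndarray) -> dict:
    totals: dict = {}
    for cat, grp in pd.Series(w).groupby(values.to_numpy()):
        totals[cat] = grp.sum()
    s = sum(totals.values())
    return {c: t / s for c, t in totals.items()}


def compute_weights(
    demographics: pd.DataFrame,
    margins: dict[str, dict[str, float]],
    characteristics: list[str] | None = None,
    method: str = "raking",
    tol: float = 1e-6,
    max_iter: int = 200,
    trim: float | None = 5.0,
) -> pd.Series:
    """Per-respondent weights matching the population margins.

    ``demographics`` must contain one row per respondent with the
    characteristic columns; the returned series is indexed like
    ``demographics`` and has mean exactly 1.  Raises if a margin category
    with nonzero target has no sample members, or on non-convergence.
    """
    chars = characteristics or [c for c in margins if c in demographics.columns]
    missing_cols = [c for c in chars if c not in demographics.columns]
    if missing_cols:
        raise ValueError(f"demographics lack characteristic columns: {missing_cols}")
    for c in chars:
        for cat, p in margins[c].items():
            if p > 0 and not (demographics[c] == cat).any():
                raise ValueError(f"empty sample cell for nonzero margin: {c}={cat!r}")
        total = sum(margins[c].values())
        if total > 1 + 1e-9:
            raise ValueError(f"margins for {c!r} sum to {total} > 1")

    n = len(demographics)
    if method == "logistic":
        w = _logistic_weights(demographics, margins, chars)
    elif method == "raking":
        w = np.ones(n)
        for it in range(max_iter):
            max_gap = 0.0
            for c in chars:
                shares = _weighted_shares(demographics[c], w)
                listed = [cat for cat in margins[c] if cat in shares]
                unlisted_share = sum(p for cat, p in shares.items() if cat not in margins[c])
                scale = (1.0 - unlisted_share) / sum(margins[c][cat] for cat in listed)
                for cat in listed:
                    target = margins[c][cat] * scale
                    ratio = target / shares[cat]
                    w[(demographics[c] == cat).to_numpy()] *= ratio
                    max_gap = max(max_gap, abs(shares[cat] - target))
            if max_gap < tol:
                break
        else:
            raise RuntimeError(f"raking did not converge in {max_iter} iterations")
    else:
        raise ValueError(f"unknown weighting method {method!r}")

    w = w / w.mean()
    if trim is not None:
        w = np.minimum(w, trim)
        w = w / w.mean()
    return pd.Series(w, index=demographics.index, name="weight")


def _logistic_weights(demographics: pd.DataFrame, margins, chars) -> np.ndarray:
    import statsmodels.api as sm

    rng = np.random.default_rng(0)  # pseudo-population draw; smooths nothing material
    n_pop = max(20000, 10 * len(demographics))
    pop = {}
    for c in chars:
        cats = list(margins[c])
        p = np.array([margins[c][cat] for cat in cats], dtype=float)
        p /= p.sum()
        pop[c] = rng.choice(cats, size=n_pop, p=p)
    pop_df = pd.DataFrame(pop)
    stacked = pd.concat([demographics[chars], pop_df], ignore_index=True)
    X = pd.get_dummies(stacked, columns=chars, drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    y = np.r_[np.ones(len(demographics)), np.zeros(n_pop)]
    fit = sm.Logit(y, X).fit(disp=0)
    p_sample = np.asarray(fit.predict(X))[: len(demographics)]
    return (1.0 - p_sample) / p_sample


def weighted_refit_delta(fit_unweighted, fit_weighted) -> pd.DataFrame:
    """Coefficient-by-coefficient differences between two fits."""
    a = fit_unweighted.coefficient_series()
    b = fit_weighted.coefficient_series()
    idx = a.index.intersection(b.index)
    return pd.DataFrame(
        {"unweighted": a[idx], "weighted": b[idx], "delta": b[idx] - a[idx]}
    )


def read_margins(path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["characteristic"], {})[row["category"]] = float(row["proportion"])
    return out


def write_margins(margins: dict[str, dict[str, float]], path) -> None:
    rows = [
        {"characteristic": c, "category": cat, "proportion": p}
        for c, cats in margins.items()
        for cat, p in cats.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
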