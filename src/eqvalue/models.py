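"""Likelihoods for cTTO and DCE valuation data and their hybrid combination.

cTTO model
    Observed disutility ``du_ij = 1 - value_ij`` for respondent *i*, state *s_j*:

        du*_ij = v_s + a_i + eps_ij,  a_i ~ N(0, tau^2),  eps_ij ~ N(0, sigma_s^2)

    with ``sigma_s = sigma_a + sigma_b * v_s`` (heteroscedasticity linear in
    the model-implied disutility of the current parameter iterate) and
    right-censoring of du* at 2 (cTTO responses cannot go below -1): an
    observation recorded at -1 contributes the upper-tail probability
    ``P(du* >= 2 | a_i)`` instead of a density.  Because the response scale
    is equally bounded above (no value beyond 1 can be expressed),
    observations recorded at 1 are by default treated symmetrically as
    left-censored at disutility 0, contributing ``P(du* <= 0 | a_i)``; set
    ``ModelSpec.ceiling_censored = False`` for the one-sided model.  The
    respondent random intercept is integrated out by fixed-order
    Gauss-Hermite quadrature (default 31 nodes).

DCE model
    Conditional logit on the same structural disutilities with scale theta:
    ``P(choose A) = logistic(theta * (du_B - du_A))``.

Hybrid model
    The weighted sum of the two log-likelihoods with shared structural
    coefficients; respondent weights multiply each respondent's contribution.

Internally parameters live on an unconstrained scale: log for tau and theta,
identity for everything else; positivity of sigma_s is enforced by rejection
(-inf log-likelihood) so sigma_a, sigma_b stay interpretable.  All gradients
are analytic (validated against finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import log_ndtr, logsumexp

from .state_space import DIMENSIONS, CoefficientSet

__all__ = [
    "ModelSpec",
    "ParameterVector",
    "CttoLikelihood",
    "DceLikelihood",
    "HybridLikelihood",
    "ctto_loglik",
    "dce_loglik",
    "hybrid_loglik",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """One of the candidate model variants.

    The study's candidate grid is {form} x {intercept} x {data} with
    heteroscedastic = random_intercept = censored = True; the extra switches
    exist for degenerate special cases (closed-form checks, starting values).
    """

    form: str = "multiplicative8"
    intercept: bool = False
    data: str = "hybrid"  # "ctto_only" | "hybrid"
    heteroscedastic: bool = True
    random_intercept: bool = True
    censored: bool = True
    ceiling_censored: bool = True  # treat values at 1 as du* <= 0 (only if censored)

    def __post_init__(self) -> None:
        if self.form not in ("multiplicative8", "additive20"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.data not in ("ctto_only", "hybrid"):
            raise ValueError(f"unknown data mode {self.data!r}")

    def label(self) -> str:
        parts = [
            "hybrid" if self.data == "hybrid" else "ctto",
            "mult8" if self.form == "multiplicative8" else "add20",
        ]
        if self.intercept:
            parts.append("intercept")
        return "_".join(parts)

    def structural_names(self) -> list[str]:
        if self.form == "multiplicative8":
            names = list(DIMENSIONS) + ["L2", "L3", "L4"]
        else:
            names = [f"{d}{l}" for d in DIMENSIONS for l in (2, 3, 4, 5)]
        if self.intercept:
            names.append("INTERCEPT")
        return names

    def param_names(self) -> list[str]:
        names = self.structural_names()
        if self.random_intercept:
            names.append("TAU")
        if self.heteroscedastic:
            names += ["SIGMA_A", "SIGMA_B"]
        else:
            names.append("SIGMA")
        if self.data == "hybrid":
            names.append("THETA")
        return names


@dataclass
class ParameterVector:
    """Named parameters of a model variant on their natural scale."""

    coeffs: CoefficientSet
    tau: float | None = None
    sigma_a: float | None = None
    sigma_b: float | None = None
    sigma: float | None = None
    theta: float | None = None

    def pack(self, spec: ModelSpec) -> np.ndarray:
        """Flatten to the unconstrained vector (log tau, log theta)."""
        x: list[float] = []
        c = self.coeffs
        if spec.form == "multiplicative8":
            x += [c.beta[d] for d in DIMENSIONS]
            assert c.levels is not None
            x += [c.levels[2], c.levels[3], c.levels[4]]
        else:
            x += [c.beta[f"{d}{l}"] for d in DIMENSIONS for l in (2, 3, 4, 5)]
        if spec.intercept:
            x.append(c.intercept if c.intercept is not None else 0.0)
        if spec.random_intercept:
            assert self.tau is not None and self.tau > 0
            x.append(np.log(self.tau))
        if spec.heteroscedastic:
            assert self.sigma_a is not None and self.sigma_b is not None
            x += [self.sigma_a, self.sigma_b]
        else:
            assert self.sigma is not None
            x.append(self.sigma)
        if spec.data == "hybrid":
            assert self.theta is not None and self.theta > 0
            x.append(np.log(self.theta))
        return np.array(x, dtype=float)

    @classmethod
    def unpack(cls, x: np.ndarray, spec: ModelSpec) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        i = 0
        if spec.form == "multiplicative8":
            beta = dict(zip(DIMENSIONS, x[:5]))
            levels = {2: x[5], 3: x[6], 4: x[7]}
            i = 8
            coeffs_kwargs = dict(form="multiplicative8", beta=beta, levels=levels)
        else:
            beta = {
                f"{d}{l}": x[k]
                for k, (d, l) in enumerate((d, l) for d in DIMENSIONS for l in (2, 3, 4, 5))
            }
            i = 20
            coeffs_kwargs = dict(form="additive20", beta=beta)
        intercept = None
        if spec.intercept:
            intercept = float(x[i])
            i += 1
        pv = cls(coeffs=CoefficientSet(intercept=intercept, **coeffs_kwargs))
        if spec.random_intercept:
            pv.tau = float(np.exp(x[i]))
            i += 1
        if spec.heteroscedastic:
            pv.sigma_a, pv.sigma_b = float(x[i]), float(x[i + 1])
            i += 2
        else:
            pv.sigma = float(x[i])
            i += 1
        if spec.data == "hybrid":
            pv.theta = float(np.exp(x[i]))
            i += 1
        return pv

    def as_series(self, spec: ModelSpec) -> pd.Series:
        """Natural-scale parameters as a named series (Table-style order)."""
        x = self.pack(spec)
        s = pd.Series(x, index=spec.param_names())
        if spec.random_intercept:
            s["TAU"] = self.tau
        if spec.data == "hybrid":
            s["THETA"] = self.theta
        return s


# -- design preparation ------------------------------------------------------


class _StructuralDesign:
    """Maps structural parameters to per-observation disutilities v and back
    (gradients), for a fixed list of observed states."""

    def __init__(self, levels: np.ndarray, spec: ModelSpec):
        self.spec = spec
        self.levels = levels  # (n, 5) ints in 1..5
        self.not_best = (levels != 1).any(axis=1).astype(float)
        if spec.form == "additive20":
            n = len(levels)
            X = np.zeros((n, 20))
            for d in range(5):
                for l in (2, 3, 4, 5):
                    X[levels[:, d] == l, d * 4 + (l - 2)] = 1.0
            self.X20 = X
        else:
            # one-hot masks per level for the L-multiplier gradients
            self.level_masks = {l: (levels == l).astype(float) for l in (2, 3, 4)}

    def v(self, x: np.ndarray) -> np.ndarray:
        """Disutility of each observation's state under structural params x."""
        spec = self.spec
        if spec.form == "multiplicative8":
            beta = x[:5]
            L = np.array([0.0, x[5], x[6], x[7], 1.0])
            v = (L[self.levels - 1] * beta).sum(axis=1)
            i = 8
        else:
            v = self.X20 @ x[:20]
            i = 20
        if spec.intercept:
            v = v + x[i] * self.not_best
        return v

    def v_grad_dot(self, x: np.ndarray, cv: np.ndarray) -> np.ndarray:
        """Given per-observation sensitivities cv = d(ll)/d(v_j), return the
        gradient with respect to the structural parameter block."""
        spec = self.spec
        if spec.form == "multiplicative8":
            beta = x[:5]
            L = np.array([0.0, x[5], x[6], x[7], 1.0])
            g = np.empty(8 + int(spec.intercept))
            Lmat = L[self.levels - 1]  # (n, 5)
            g[:5] = Lmat.T @ cv
            for k, l in enumerate((2, 3, 4)):
                g[5 + k] = cv @ (self.level_masks[l] @ beta)
            i = 8
        else:
            g = np.empty(20 + int(spec.intercept))
            g[:20] = self.X20.T @ cv
            i = 20
        if spec.intercept:
            g[i] = cv @ self.not_best
        return g


def _norm_logpdf(z: np.ndarray) -> np.ndarray:
    return -0.5 * z * z - _LOG_SQRT_2PI


# -- cTTO likelihood ---------------------------------------------------------


class CttoLikelihood:
    """Prepared cTTO data with log-likelihood and analytic gradient.

    Respondent weights default to 1.  ``weights`` may be a mapping or pandas
    Series keyed by respondent id.
    """

    def __init__(
        self,
        ctto: pd.DataFrame,
        spec: ModelSpec,
        weights=None,
        n_quad: int = 31,
    ):
        if len(ctto) == 0:
            raise ValueError("empty cTTO data")
        self.spec = spec
        df = ctto.sort_values("respondent_id", kind="stable").reset_index(drop=True)
        resp_ids, resp_idx = np.unique(df["respondent_id"].to_numpy(), return_inverse=True)
        self.resp_ids = resp_ids
        self.resp_idx = resp_idx
        self.starts = np.searchsorted(resp_idx, np.arange(len(resp_ids)))
        values = df["value"].to_numpy(dtype=float)
        self.du = 1.0 - values
        if spec.censored:
            self.cens = values <= -1.0 + 1e-9
            self.ceil = (values >= 1.0 - 1e-9) if spec.ceiling_censored else np.zeros(
                len(df), dtype=bool
            )
        else:
            self.cens = np.zeros(len(df), dtype=bool)
            self.ceil = np.zeros(len(df), dtype=bool)
        levels = np.array([[int(c) for c in code] for code in df["state_code"]])
        self.design = _StructuralDesign(levels, spec)
        self.w_resp = _resolve_weights(weights, resp_ids)
        self.n_resp = len(resp_ids)
        nodes, wts = hermgauss(n_quad if spec.random_intercept else 1)
        self.gh_x = nodes
        self.gh_logw = np.log(wts) - 0.5 * np.log(np.pi)
        self._n_struct = len(spec.structural_names())

    def loglik_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        spec = self.spec
        ns = self._n_struct
        i = ns
        if spec.random_intercept:
            log_tau = x[i]
            tau = np.exp(log_tau)
            i += 1
        else:
            tau = 0.0
        if spec.heteroscedastic:
            sigma_a, sigma_b = x[i], x[i + 1]
            i_sig = i
            i += 2
        else:
            sigma_const = x[i]
            i_sig = i
            i += 1

        v = self.design.v(x[:ns])
        sigma = sigma_a + sigma_b * v if spec.heteroscedastic else np.full_like(v, sigma_const)
        if np.any(sigma <= 0):
            return -np.inf, np.zeros_like(x)

        a = np.sqrt(2.0) * tau * self.gh_x  # (K,)
        K = len(a)
        unc = ~(self.cens | self.ceil)
        # log-contribution matrix G (K, n_obs) and primitives for the gradient
        G = np.empty((K, len(v)))
        resid = self.du[unc][None, :] - v[unc][None, :] - a[:, None]
        z = resid / sigma[unc][None, :]
        G[:, unc] = _norm_logpdf(z) - np.log(sigma[unc])[None, :]
        if self.cens.any():
            c = (2.0 - v[self.cens][None, :] - a[:, None]) / sigma[self.cens][None, :]
            G[:, self.cens] = log_ndtr(-c)
        if self.ceil.any():
            c0 = (0.0 - v[self.ceil][None, :] - a[:, None]) / sigma[self.ceil][None, :]
            G[:, self.ceil] = log_ndtr(c0)

        S = np.add.reduceat(G, self.starts, axis=1)  # (K, n_resp)
        li = logsumexp(S + self.gh_logw[:, None], axis=0)
        ll = float(self.w_resp @ li)

        # posterior node weights and observation-level weights
        pi = np.exp(S + self.gh_logw[:, None] - li[None, :])  # (K, n_resp)
        Wobs = pi[:, self.resp_idx] * self.w_resp[self.resp_idx][None, :]

        Dv = np.empty((K, len(v)))  # d log g / d v at fixed sigma (= d/d a)
        Dsig = np.empty((K, len(v)))  # d log g / d sigma
        Dv[:, unc] = z / sigma[unc][None, :]
        Dsig[:, unc] = (z * z - 1.0) / sigma[unc][None, :]
        if self.cens.any():
            h = np.exp(_norm_logpdf(c) - log_ndtr(-c))  # hazard at c
            Dv[:, self.cens] = h / sigma[self.cens][None, :]
            Dsig[:, self.cens] = h * c / sigma[self.cens][None, :]
        if self.ceil.any():
            h0 = np.exp(_norm_logpdf(c0) - log_ndtr(c0))  # reverse hazard at c0
            Dv[:, self.ceil] = -h0 / sigma[self.ceil][None, :]
            Dsig[:, self.ceil] = -h0 * c0 / sigma[self.ceil][None, :]

        grad = np.zeros_like(x)
        WD_sig = Wobs * Dsig
        cv = (Wobs * Dv).sum(axis=0)  # total d ll / d v_j at fixed sigma
        if spec.heteroscedastic:
            csig = WD_sig.sum(axis=0)
            cv = cv + sigma_b * csig
            grad[i_sig] = csig.sum()
            grad[i_sig + 1] = csig @ v
        else:
            grad[i_sig] = WD_sig.sum()
        grad[:ns] = self.design.v_grad_dot(x[:ns], cv)
        if spec.random_intercept:
            # d a_k / d log tau = a_k
            grad[ns] = ((Wobs * Dv).sum(axis=1) * a).sum()
        return ll, grad


# -- DCE likelihood ----------------------------------------------------------


class DceLikelihood:
    """Prepared DCE data: conditional-logit log-likelihood and gradient."""

    def __init__(self, dce: pd.DataFrame, spec: ModelSpec, weights=None):
        if len(dce) == 0:
            raise ValueError("empty DCE data")
        self.spec = spec
        levels_a = np.array([[int(c) for c in code] for code in dce["state_a"]])
        levels_b = np.array([[int(c) for c in code] for code in dce["state_b"]])
        self.design_a = _StructuralDesign(levels_a, spec)
        self.design_b = _StructuralDesign(levels_b, spec)
        self.y = dce["chose_a"].to_numpy(dtype=float)
        resp = dce["respondent_id"].to_numpy()
        ids = np.unique(resp)
        w = _resolve_weights(weights, ids)
        w_of = dict(zip(ids, w))
        self.w = np.array([w_of[r] for r in resp])
        self._n_struct = len(spec.structural_names())

    def loglik_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        ns = self._n_struct
        log_theta = x[-1]
        theta = np.exp(log_theta)
        xs = x[:ns]
        delta = self.design_b.v(xs) - self.design_a.v(xs)
        eta = theta * delta
        # log p(choice): -log(1+e^-eta) if A chosen, -eta - log(1+e^-eta) if B
        log_p_a = -np.logaddexp(0.0, -eta)
        ll = float(self.w @ (self.y * log_p_a + (1.0 - self.y) * (log_p_a - eta)))
        p = np.exp(log_p_a)
        r = self.w * (self.y - p)  # d ll / d eta per pair
        grad = np.zeros_like(x)
        grad[-1] = (r @ delta) * theta  # log-theta scale
        cv = r * theta
        grad[:ns] = self.design_b.v_grad_dot(xs, cv) - self.design_a.v_grad_dot(xs, cv)
        return ll, grad


# -- hybrid ------------------------------------------------------------------


class HybridLikelihood:
    """Joint cTTO + DCE likelihood with shared structural coefficients."""

    def __init__(self, dataset, spec: ModelSpec, weights=None, n_quad: int = 31):
        self.spec = spec
        self.ctto = (
            CttoLikelihood(dataset.ctto, spec, weights, n_quad)
            if len(dataset.ctto)
            else None
        )
        self.dce = (
            DceLikelihood(dataset.dce, spec, weights)
            if spec.data == "hybrid" and len(dataset.dce)
            else None
        )
        if self.ctto is None and self.dce is None:
            raise ValueError("dataset has neither cTTO nor DCE rows")
        # normaliser for the optimizer's scaled objective
        if self.ctto is not None:
            self.total_weight = float(self.ctto.w_resp.sum())
        else:
            self.total_weight = float(len(np.unique(dataset.dce["respondent_id"])))

    def loglik_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        ll = 0.0
        grad = np.zeros_like(np.asarray(x, dtype=float))
        if self.ctto is not None:
            ll_c, g_c = self.ctto.loglik_and_grad(x)
            if not np.isfinite(ll_c):
                return -np.inf, grad
            ll += ll_c
            grad += g_c
        if self.dce is not None:
            ll_d, g_d = self.dce.loglik_and_grad(x)
            ll += ll_d
            grad += g_d
        return ll, grad


def _resolve_weights(weights, ids: np.ndarray) -> np.ndarray:
    if weights is None:
        return np.ones(len(ids))
    if isinstance(weights, pd.Series):
        return weights.reindex(ids).to_numpy(dtype=float)
    if isinstance(weights, dict):
        return np.array([weights[i] for i in ids], dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(ids):
        raise ValueError("weight vector length does not match number of respondents")
    return w


# -- public functional API ---------------------------------------------------


def ctto_loglik(
    params: ParameterVector, spec: ModelSpec, ctto_data: pd.DataFrame, weights=None, n_quad: int = 31
) -> float:
    """Weighted cTTO log-likelihood at the given natural-scale parameters."""
    engine = CttoLikelihood(ctto_data, spec, weights, n_quad)
    return engine.loglik_and_grad(params.pack(spec))[0]


def dce_loglik(params: ParameterVector, spec: ModelSpec, dce_data: pd.DataFrame, weights=None) -> float:
    """Weighted DCE conditional-logit log-likelihood."""
    if params.theta is None or params.theta <= 0:
        raise ValueError("theta must be > 0 for the DCE likelihood")
    engine = DceLikelihood(dce_data, spec, weights)
    return engine.loglik_and_grad(params.pack(spec))[0]


def hybrid_loglik(params: ParameterVector, spec: ModelSpec, dataset, weights=None, n_quad: int = 31) -> float:
    """Joint log-likelihood: cTTO part plus DCE part (when present)."""
    ll = 0.0
    if len(dataset.ctto):
        ll += ctto_loglik(params, spec, dataset.ctto, weights, n_quad)
    if spec.data == "hybrid" and len(dataset.dce):
        ll += dce_loglik(params, spec, dataset.dce, weights)
    return ll
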