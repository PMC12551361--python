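"""Ordered probit regression for 3-class cognitive status.

The latent variable is an *impairment index* z = xβ + ε with ε ~ N(0, 1):
larger fitted index means worse cognition and hence higher dementia
probability.  Cutpoints κ1 < κ2 partition the latent scale so that

    P(normal)   = Φ(κ1 − xβ)
    P(CIND)     = Φ(κ2 − xβ) − Φ(κ1 − xβ)
    P(dementia) = 1 − Φ(κ2 − xβ)

Class codes follow :mod:`dementia_cohorts.simulate`: 0 = dementia,
1 = cognitively impaired not demented, 2 = normal, i.e. impairment level
is ``2 − class``.  The fit is maximum likelihood via quasi-Newton ascent
on a reparameterized cutpoint gap (κ2 = κ1 + exp(g), which enforces
κ1 < κ2 without constraints), with a small multi-start guard against
local optima.  When only two (extreme) classes are present the same code
path reduces to a binary probit with a single cutpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import optimize
from scipy.special import log_ndtr, ndtr

_LOG_TINY = np.log(np.finfo(float).tiny)


class RankDeficientError(np.linalg.LinAlgError):
    """Feature matrix is rank deficient; names the offending columns."""


class SeparationError(RuntimeError):
    """Likelihood is unbounded (perfect separation); names the columns."""


@dataclass
class OrderedProbitModel:
    """Fitted ordered-probit coefficients and cutpoints."""

    respondent_kind: str
    feature_names: tuple[str, ...]
    beta: np.ndarray
    kappa: np.ndarray  # strictly increasing cutpoints on the latent scale
    loglik: float
    n_obs: int
    converged: bool
    beta_se: np.ndarray | None = None
    kappa_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if not np.all(np.diff(self.kappa) > 0):
            raise ValueError(f"cutpoints must be strictly increasing: {self.kappa}")
        if len(self.feature_names) != self.beta.size:
            raise ValueError("beta dimension does not match feature names")

    # -- serialization (structured text) ---------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "respondent_kind": self.respondent_kind,
            "feature_names": list(self.feature_names),
            "beta": [float(b) for b in self.beta],
            "kappa": [float(k) for k in self.kappa],
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OrderedProbitModel":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            respondent_kind=raw["respondent_kind"],
            feature_names=tuple(raw["feature_names"]),
            beta=np.array(raw["beta"]),
            kappa=np.array(raw["kappa"]),
            loglik=raw["loglik"],
            n_obs=raw["n_obs"],
            converged=raw["converged"],
        )


def _impairment(y: np.ndarray) -> np.ndarray:
    """Map class codes (0=dementia, 1=CIND, 2=normal) to impairment 0..K−1."""
    return 2 - np.asarray(y, dtype=int)


def _unpack(theta: np.ndarray, p: int, n_cut: int) -> tuple[np.ndarray, np.ndarray]:
    beta = theta[:p]
    alpha = theta[p:]
    kappa = np.empty(n_cut)
    kappa[0] = alpha[0]
    if n_cut > 1:
        kappa[1:] = alpha[0] + np.cumsum(np.exp(alpha[1:]))
    return beta, kappa


def _log_cell_prob(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """log(Φ(upper) − Φ(lower)) with ±inf bounds, computed tail-stably."""
    out = np.empty(lower.shape)
    lo_inf = np.isneginf(lower)
    hi_inf = np.isposinf(upper)
    mid = ~lo_inf & ~hi_inf
    out[lo_inf] = log_ndtr(upper[lo_inf])
    out[hi_inf] = log_ndtr(-lower[hi_inf])
    if mid.any():
        u, l = upper[mid], lower[mid]
        # evaluate the difference in whichever tail is smaller
        diff = np.where(u + l > 0, ndtr(-l) - ndtr(-u), ndtr(u) - ndtr(l))
        out[mid] = np.log(np.clip(diff, np.finfo(float).tiny, None))
    return np.maximum(out, _LOG_TINY)


def _negloglik_and_grad(
    theta: np.ndarray, X: np.ndarray, d: np.ndarray, n_cut: int
) -> tuple[float, np.ndarray]:
    n, p = X.shape
    beta, kappa = _unpack(theta, p, n_cut)
    eta = X @ beta
    kpad = np.concatenate(([-np.inf], kappa, [np.inf]))
    lower = kpad[d] - eta
    upper = kpad[d + 1] - eta
    logp = _log_cell_prob(lower, upper)
    P = np.exp(logp)

    inv_sqrt2pi = 1.0 / np.sqrt(2 * np.pi)
    u_fin = np.where(np.isfinite(upper), upper, 0.0)
    l_fin = np.where(np.isfinite(lower), lower, 0.0)
    phi_u = np.where(np.isfinite(upper), np.exp(-0.5 * u_fin**2) * inv_sqrt2pi, 0.0)
    phi_l = np.where(np.isfinite(lower), np.exp(-0.5 * l_fin**2) * inv_sqrt2pi, 0.0)
    ru = phi_u / P
    rl = phi_l / P

    # dl/d eta and per-cutpoint contributions
    dl_deta = rl - ru
    grad_beta = X.T @ dl_deta  # gradient of +loglik
    dl_dkappa = np.zeros((n, n_cut))
    ii = np.arange(n)
    up_idx = d  # kappa index of the upper bound is d (0-based) when d < n_cut
    has_up = d < n_cut
    dl_dkappa[ii[has_up], up_idx[has_up]] += ru[has_up]
    lo_idx = d - 1
    has_lo = d >= 1
    dl_dkappa[ii[has_lo], lo_idx[has_lo]] -= rl[has_lo]
    gk = dl_dkappa.sum(axis=0)

    grad_alpha = np.empty(n_cut)
    grad_alpha[0] = gk.sum()
    if n_cut > 1:
        alpha = theta[p:]
        tail = np.cumsum(gk[::-1])[::-1]  # sum_{j>=m} gk[j]
        grad_alpha[1:] = np.exp(alpha[1:]) * tail[1:]

    nll = -float(logp.sum())
    grad = -np.concatenate([grad_beta, grad_alpha])
    return nll, grad


def _check_design(X: np.ndarray, names: tuple[str, ...]) -> None:
    if X.shape[0] <= X.shape[1] + 2:
        raise ValueError(
            f"need n > n_features + 2 observations, got n={X.shape[0]}, p={X.shape[1]}"
        )
    if X.shape[1] == 0:
        return
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[0] > 0 and sv[-1] / sv[0] < 1e-10:
        _, _, vt = np.linalg.svd(X)
        null = np.abs(vt[-1])
        bad = [names[j] for j in np.flatnonzero(null > 0.1)]
        raise RankDeficientError(f"rank-deficient feature matrix; columns involved: {bad}")


def fit_ordered_probit(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    respondent_kind: str = "self",
    n_starts: int = 3,
    gtol: float = 1e-6,
    seed: int = 0,
    ridge: float = 0.0,
) -> OrderedProbitModel:
    """Maximum-likelihood ordered probit for 3-class cognitive status.

    ``y`` uses class codes 0 = dementia, 1 = CIND, 2 = normal.  If the
    middle class is absent (binary data coded {0, 2}), a single-cutpoint
    (binary probit) model is fitted instead.  Non-convergence is reported
    through ``converged=False``, never silently.

    ``ridge`` adds an L2 penalty ridge/2·‖β‖² on the slopes (not the
    cutpoints) — a weakly informative guard for small, quasi-separated
    calibration samples.  With a penalty the separation diagnostic is
    disabled and the reported log-likelihood stays the unpenalized one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    names = tuple(feature_names) if feature_names else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    _check_design(X, names)
    classes = np.unique(y)
    if not np.isin(classes, [0, 1, 2]).all():
        raise ValueError(f"labels must be in {{0,1,2}}, got {classes}")
    if classes.size < 2:
        raise ValueError("need at least two classes present")

    d_all = _impairment(y)
    # compress to the observed ordered levels (handles the binary reduction)
    levels = np.unique(d_all)
    d = np.searchsorted(levels, d_all)
    n_cut = levels.size - 1
    n, p = X.shape

    # start from empirical cumulative shares (β = 0 closed form)
    shares = np.bincount(d, minlength=levels.size) / n
    cum = np.clip(np.cumsum(shares)[:-1], 1e-6, 1 - 1e-6)
    kappa0 = np.array([float(_ndtri(c)) for c in cum])
    alpha0 = np.empty(n_cut)
    alpha0[0] = kappa0[0]
    if n_cut > 1:
        alpha0[1:] = np.log(np.maximum(np.diff(kappa0), 1e-3))
    theta0 = np.concatenate([np.zeros(p), alpha0])

    def mean_obj(theta: np.ndarray) -> tuple[float, np.ndarray]:
        f, g = _negloglik_and_grad(theta, X, d, n_cut)
        if ridge > 0:
            b = theta[:p]
            f = f + 0.5 * ridge * float(b @ b)
            g = g.copy()
            g[:p] += ridge * b
        return f / n, g / n

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 + rng.normal(0, 0.2, size=theta0.size)
        res = optimize.minimize(
            mean_obj,
            start,
            jac=True,
            method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    beta, kappa = _unpack(best.x, p, n_cut)
    if ridge == 0.0 and np.abs(beta).max(initial=0.0) > 25.0:
        bad = [names[j] for j in np.flatnonzero(np.abs(beta) > 25.0)]
        raise SeparationError(
            f"coefficients diverged (likely perfect separation) in columns: {bad}"
        )
    converged = bool(best.success or np.linalg.norm(best.jac, ord=np.inf) < 1e-5)
    loglik = -float(best.fun) * n
    if ridge > 0:  # report the unpenalized likelihood at the penalized optimum
        nll_plain, _ = _negloglik_and_grad(best.x, X, d, n_cut)
        loglik = -float(nll_plain)

    beta_se, kappa_se = _asymptotic_se(best.x, X, d, n_cut, p)
    return OrderedProbitModel(
        respondent_kind=respondent_kind,
        feature_names=names,
        beta=beta,
        kappa=kappa,
        loglik=loglik,
        n_obs=n,
        converged=converged,
        beta_se=beta_se,
        kappa_se=kappa_se,
    )


def loglik_at(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, kappa: np.ndarray
) -> float:
    """Ordered-probit log-likelihood at arbitrary (β, κ); grid-search helper."""
    X = np.asarray(X, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    d_all = _impairment(np.asarray(y, dtype=int))
    levels = np.unique(d_all)
    d = np.searchsorted(levels, d_all)
    eta = X @ np.asarray(beta, dtype=float)
    kpad = np.concatenate(([-np.inf], kappa, [np.inf]))
    return float(_log_cell_prob(kpad[d] - eta, kpad[d + 1] - eta).sum())


def _ndtri(q: float) -> float:
    from scipy.special import ndtri

    return ndtri(q)


def _asymptotic_se(
    theta: np.ndarray, X: np.ndarray, d: np.ndarray, n_cut: int, p: int
) -> tuple[np.ndarray, np.ndarray]:
    """Observed-information SEs for (β, κ) via the delta method."""
    k = theta.size
    eps = 1e-5
    H = np.zeros((k, k))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps
        tm[j] -= eps
        _, gp = _negloglik_and_grad(tp, X, d, n_cut)
        _, gm = _negloglik_and_grad(tm, X, d, n_cut)
        H[:, j] = (gp - gm) / (2 * eps)
    H = 0.5 * (H + H.T)
    try:
        cov_theta = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan), np.full(n_cut, np.nan)
    # Jacobian of (β, κ) wrt θ = (β, α)
    J = np.eye(k)
    if n_cut > 1:
        alpha = theta[p:]
        for j in range(1, n_cut):
            for m in range(1, j + 1):
                J[p + j, p + m] = np.exp(alpha[m])
            J[p + j, p] = 1.0
    cov = J @ cov_theta @ J.T
    var = np.clip(np.diag(cov), 0, None)
    return np.sqrt(var[:p]), np.sqrt(var[p:])


def class_probabilities(model: OrderedProbitModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities, columns ordered (dementia, CIND, normal).

    For the full 3-class model: p_dementia = 1 − Φ(κ2 − xβ),
    p_normal = Φ(κ1 − xβ); each row sums to one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.beta.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {model.beta.size}"
        )
    eta = X @ model.beta
    kpad = np.concatenate(([-np.inf], model.kappa, [np.inf]))
    n_levels = model.kappa.size + 1
    # impairment level k occupies (kpad[k], kpad[k+1])
    cum = ndtr(kpad[None, :] - eta[:, None])  # (n, n_levels+1)
    probs_impairment = np.diff(cum, axis=1)  # columns: impairment 0..K−1
    if n_levels == 3:
        probs = probs_impairment[:, ::-1]  # (dementia, cind, normal)
    else:  # binary reduction {normal, dementia}
        probs = np.column_stack(
            [probs_impairment[:, 1], np.zeros(len(eta)), probs_impairment[:, 0]]
        )
    return probs
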