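"""Binary GLM / GLMM estimation for panel outcomes.

Two fitting paths share one interface:

* ``RandomInterceptGLMM`` — maximum likelihood for a binary probit or
  logit model with a person-level normal random intercept.  The marginal
  likelihood of each person integrates the intercept out by *adaptive*
  Gauss–Hermite quadrature: nodes are recentred at each person's posterior
  mode and rescaled by the local curvature, so few nodes (default 9)
  suffice even for long panels.  The score is evaluated holding the
  adapted nodes fixed (the mode is a stationary point of the integrand,
  so the neglected correction is higher order).
* ``fit_plain_glm`` — ordinary ML probit/logit via Newton–Raphson, used
  when no random effect is requested.

Both paths report model-based and cluster-robust (sandwich, clustered on
person) standard errors; for the GLMM the person-level marginal
likelihood factorizes over clusters, so per-person score contributions
give the sandwich meat directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, log_ndtr

_SQRT2 = np.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _lam_probit(a: np.ndarray) -> np.ndarray:
    """Inverse Mills ratio φ(a)/Φ(a), tail-stable."""
    return np.exp(-0.5 * a * a - _LOG_SQRT_2PI - log_ndtr(a))


def _loglik_terms(link: str, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log F(a), dlogF/da) for the chosen link at signed arguments a."""
    if link == "probit":
        return log_ndtr(a), _lam_probit(a)
    if link == "logit":
        # log sigmoid(a) = -softplus(-a); derivative sigmoid(-a)
        return -np.logaddexp(0.0, -a), expit(-a)
    raise ValueError(f"unknown link {link!r}")


@dataclass
class GLMMResult:
    beta: np.ndarray
    sigma_u: float
    loglik: float
    se_model: np.ndarray
    se_cluster: np.ndarray
    converged: bool
    n_obs: int
    n_clusters: int
    n_quad: int = 0


class RandomInterceptGLMM:
    """Marginal ML for y_ij ~ Bernoulli(F(x_ij'β + u_i)), u_i ~ N(0, σ²)."""

    MIN_LOG_SIGMA = -9.0  # σ ≈ 1.2e-4: effectively a plain GLM
    MAX_LOG_SIGMA = 3.0

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        clusters: np.ndarray,
        link: str = "probit",
        n_quad: int = 9,
    ) -> None:
        if n_quad < 3:
            raise ValueError("need at least 3 quadrature nodes")
        order = np.argsort(clusters, kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.X = np.asarray(X, dtype=float)[order]
        cl = np.asarray(clusters)[order]
        _, self.cluster_index, counts = np.unique(
            cl, return_inverse=True, return_counts=True
        )
        self.n_clusters = counts.size
        self.max_m = int(counts.max())
        self.n, self.p = self.X.shape
        self.link = link
        self.nodes, self.weights = hermgauss(n_quad)
        self.n_quad = n_quad

        # pad observations into (n_clusters, max_m) with a mask
        pos = np.zeros(self.n, dtype=int)
        seen: dict[int, int] = {}
        for i, c in enumerate(self.cluster_index):
            pos[i] = seen.get(c, 0)
            seen[c] = pos[i] + 1
        self._rows = (self.cluster_index, pos)
        self.mask = np.zeros((self.n_clusters, self.max_m), dtype=bool)
        self.mask[self._rows] = True
        self.s_pad = np.zeros((self.n_clusters, self.max_m))
        self.s_pad[self._rows] = 2.0 * self.y - 1.0
        self._mode = np.zeros(self.n_clusters)  # warm start across evals

    def _pad(self, values: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n_clusters, self.max_m))
        out[self._rows] = values
        return out

    # -- integrand pieces -------------------------------------------------
    def _find_modes(self, eta_pad: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode and curvature scale per cluster (damped Newton)."""
        u = self._mode.copy()
        for _ in range(25):
            a = self.s_pad * (eta_pad + u[:, None])
            _, lam = _loglik_terms(self.link, a)
            lam = np.where(self.mask, lam, 0.0)
            grad = (self.s_pad * lam).sum(axis=1) - u / sigma**2
            if self.link == "probit":
                curv = (lam * (np.where(self.mask, a, 0.0) + lam)).sum(axis=1)
            else:
                curv = (lam * (1.0 - lam) * self.mask).sum(axis=1)
            hess = -curv - 1.0 / sigma**2
            step = grad / hess
            # dampen long steps for stability
            step = np.clip(step, -4.0 * sigma - 1.0, 4.0 * sigma + 1.0)
            u = u - step
            if np.max(np.abs(step)) < 1e-9:
                break
        a = self.s_pad * (eta_pad + u[:, None])
        _, lam = _loglik_terms(self.link, a)
        lam = np.where(self.mask, lam, 0.0)
        if self.link == "probit":
            curv = (lam * (np.where(self.mask, a, 0.0) + lam)).sum(axis=1)
        else:
            curv = (lam * (1.0 - lam) * self.mask).sum(axis=1)
        tau = 1.0 / np.sqrt(curv + 1.0 / sigma**2)
        self._mode = u
        return u, tau

    def _cluster_logliks_and_scores(
        self, theta: np.ndarray, want_scores: bool
    ) -> tuple[np.ndarray, np.ndarray | None]:
        beta = theta[: self.p]
        sigma = float(np.exp(theta[self.p]))
        eta = self.X @ beta
        eta_pad = self._pad(eta)
        mode, tau = self._find_modes(eta_pad, sigma)

        # u_{ck} = mode_c + sqrt(2) tau_c z_k
        u = mode[:, None] + _SQRT2 * tau[:, None] * self.nodes[None, :]
        a = self.s_pad[:, None, :] * (eta_pad[:, None, :] + u[:, :, None])
        logF, lam = _loglik_terms(self.link, a)
        logF = np.where(self.mask[:, None, :], logF, 0.0)
        h = logF.sum(axis=2) - 0.5 * (u / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI
        log_terms = np.log(self.weights)[None, :] + self.nodes[None, :] ** 2 + h
        m = log_terms.max(axis=1, keepdims=True)
        sumexp = np.exp(log_terms - m).sum(axis=1)
        ll = np.log(sumexp) + m[:, 0] + 0.5 * np.log(2.0) + np.log(tau)

        if not want_scores:
            return ll, None

        omega = np.exp(log_terms - m) / sumexp[:, None]  # (C, Q) posterior weights
        lam = np.where(self.mask[:, None, :], lam, 0.0)
        # dh/d eta_j = s_j lam_j ; accumulate back to observation rows
        w_obs = (omega[:, :, None] * self.s_pad[:, None, :] * lam).sum(axis=1)
        scores_beta_obs = w_obs[self._rows][:, None] * self.X  # (n, p)
        scores_beta = np.zeros((self.n_clusters, self.p))
        np.add.at(scores_beta, self.cluster_index, scores_beta_obs)
        dh_dlogsig = (u / sigma) ** 2 - 1.0
        scores_ls = (omega * dh_dlogsig).sum(axis=1)
        return ll, np.column_stack([scores_beta, scores_ls])

    def negloglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, scores = self._cluster_logliks_and_scores(theta, want_scores=True)
        return -float(ll.sum()) / self.n, -scores.sum(axis=0) / self.n

    def fit(
        self,
        beta0: np.ndarray | None = None,
        sigma0: float = 0.5,
        compute_se: bool = True,
    ) -> GLMMResult:
        if beta0 is None:
            beta0 = fit_plain_glm(self.y, self.X, self.cluster_index, self.link).beta
        # keep quasi-separated GLM starts inside a sane region
        theta0 = np.concatenate([np.clip(beta0, -8.0, 8.0), [np.log(sigma0)]])
        bounds = [(None, None)] * self.p + [(self.MIN_LOG_SIGMA, self.MAX_LOG_SIGMA)]
        res = optimize.minimize(
            self.negloglik_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
        )
        theta = res.x
        ll, scores = self._cluster_logliks_and_scores(theta, want_scores=True)

        k = self.p + 1
        if compute_se:
            H = self._observed_information(theta)
            try:
                bread = np.linalg.inv(H)
                se_model_full = np.sqrt(np.clip(np.diag(bread), 0, None))
                meat = scores.T @ scores
                cov_cl = bread @ meat @ bread
                se_cluster_full = np.sqrt(np.clip(np.diag(cov_cl), 0, None))
            except np.linalg.LinAlgError:
                se_model_full = np.full(k, np.nan)
                se_cluster_full = np.full(k, np.nan)
        else:
            se_model_full = np.full(k, np.nan)
            se_cluster_full = np.full(k, np.nan)

        sigma = float(np.exp(theta[self.p]))
        at_floor = theta[self.p] <= self.MIN_LOG_SIGMA + 1e-6
        converged = bool(res.success or np.linalg.norm(res.jac, np.inf) < 1e-5 or at_floor)
        return GLMMResult(
            beta=theta[: self.p],
            sigma_u=0.0 if at_floor else sigma,
            loglik=float(ll.sum()),
            se_model=se_model_full[: self.p],
            se_cluster=se_cluster_full[: self.p],
            converged=converged,
            n_obs=self.n,
            n_clusters=self.n_clusters,
            n_quad=self.n_quad,
        )

    def _observed_information(self, theta: np.ndarray) -> np.ndarray:
        """Total-loglik Hessian by central differences of the analytic score."""
        k = theta.size
        H = np.zeros((k, k))
        eps = 1e-5
        for j in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            _, gp = self._cluster_logliks_and_scores(tp, want_scores=True)
            _, gm = self._cluster_logliks_and_scores(tm, want_scores=True)
            H[:, j] = -(gp.sum(axis=0) - gm.sum(axis=0)) / (2 * eps)
        return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# plain GLM (no random effect)
# ---------------------------------------------------------------------------

def fit_plain_glm(
    y: np.ndarray,
    X: np.ndarray,
    clusters: np.ndarray,
    link: str = "probit",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GLMMResult:
    """Binary probit/logit ML via Newton–Raphson with sandwich SEs."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    s = 2.0 * y - 1.0

    def pieces(beta: np.ndarray):
        """(loglik, per-obs score rows, Fisher weights) at beta."""
        eta = X @ beta
        a = s * eta
        logF, lam = _loglik_terms(link, a)
        g_obs = (s * lam)[:, None] * X
        if link == "probit":
            # expected information: φ(η)² / (Φ(η)(1−Φ(η))), tail-stable
            log_phi = -0.5 * eta * eta - _LOG_SQRT_2PI
            w = np.exp(2 * log_phi - log_ndtr(eta) - log_ndtr(-eta))
        else:
            mu = expit(eta)
            w = mu * (1.0 - mu)
        return float(logF.sum()), g_obs, w

    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, g_obs, w = pieces(beta)
        grad = g_obs.sum(axis=0)
        H = (X * w[:, None]).T @ X  # Fisher information (positive definite)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if abs(ll - ll_old) < tol and np.abs(step).max() < 1e-8:
            converged = True
            break
        ll_old = ll
    ll, g_obs, w = pieces(beta)
    grad = g_obs.sum(axis=0)
    H = (X * w[:, None]).T @ X
    # pinv tolerates saturated cells (zero IRLS weight on a column's support)
    se_model = np.sqrt(np.clip(np.diag(np.linalg.pinv(H)), 0, None))
    # sandwich bread: observed information (matches HC0 when clusters are singletons)
    a = s * (X @ beta)
    _, lam = _loglik_terms(link, a)
    w_obs = lam * (a + lam) if link == "probit" else lam * (1.0 - lam)
    bread = np.linalg.pinv((X * w_obs[:, None]).T @ X)
    cl = np.asarray(clusters)
    _, idx = np.unique(cl, return_inverse=True)
    G = np.zeros((idx.max() + 1, p))
    np.add.at(G, idx, g_obs)
    cov_cl = bread @ (G.T @ G) @ bread
    se_cluster = np.sqrt(np.clip(np.diag(cov_cl), 0, None))
    if not converged and np.abs(grad).max() < 1e-6 * n:
        converged = True
    return GLMMResult(
        beta=beta,
        sigma_u=0.0,
        loglik=ll,
        se_model=se_model,
        se_cluster=se_cluster,
        converged=converged,
        n_obs=n,
        n_clusters=int(idx.max() + 1),
    )
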