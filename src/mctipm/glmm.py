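"""Penalized-likelihood inference for one-way random-intercept GLMs.

Supported families: ``gaussian`` (identity link), ``binomial`` (logit link,
optional per-row trial counts) and ``poisson`` (log link).  The model is

    eta = X beta + u[group],   u_j ~ Normal(0, sigma_u^2)

with weakly informative Normal priors on the fixed effects (a scalar or
per-coefficient vector of prior SDs; default SD 10).
Fitting alternates two steps until the variance component stabilizes:

1. a damped Newton maximization of the penalized log-likelihood over
   (beta, u) at the current sigma_u (for the Gaussian family this is an
   exact ridge solve, with the residual SD profiled by maximum
   likelihood);
2. an EM-style update of sigma_u^2 using the Laplace posterior of the
   group effects, sigma_u^2 <- mean_j(u_j^2 + Var(u_j)), which avoids the
   degenerate sigma_u -> 0 collapse of joint MAP estimation.

The posterior over (beta, u, log sigma_e) is then approximated by a
Gaussian at the mode with the analytic Hessian, from which the requested
number of draws is taken; these Laplace draws stand in for MCMC draws
throughout the pipeline (sigma_u itself is held at its EM estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

PRIOR_SD_BETA = 10.0
SIGMA_U_FLOOR = 1e-4


class DegenerateFitError(ValueError):
    """Raised when a response carries no information (e.g. constant 0/1)."""


@dataclass
class LaplaceFit:
    """Penalized-likelihood fit with a Gaussian (Laplace) posterior."""

    family: str
    beta: np.ndarray
    u: np.ndarray
    group_labels: tuple
    sigma_group: float
    sigma_resid: float | None
    mode: np.ndarray            # (beta, u[, log sigma_e])
    cov: np.ndarray
    draws: np.ndarray           # (n_draws, dim)
    n_obs: int
    _X: np.ndarray = field(repr=False)
    _y: np.ndarray = field(repr=False)
    _trials: np.ndarray | None = field(repr=False)
    _group_idx: np.ndarray | None = field(repr=False)

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    @property
    def q(self) -> int:
        return self.u.shape[0]

    def beta_draws(self) -> np.ndarray:
        return self.draws[:, : self.p]

    def sigma_resid_draws(self) -> np.ndarray | None:
        if self.family != "gaussian":
            return None
        return np.exp(self.draws[:, -1])

    def beta_cov(self) -> np.ndarray:
        return self.cov[: self.p, : self.p]

    def loglik_matrix(self) -> np.ndarray:
        """Pointwise conditional log-likelihood, one row per posterior draw."""
        X, y, m, gidx = self._X, self._y, self._trials, self._group_idx
        eta = self.draws[:, : self.p] @ X.T
        if gidx is not None and self.q:
            eta = eta + self.draws[:, self.p: self.p + self.q][:, gidx]
        if self.family == "gaussian":
            sig = np.exp(self.draws[:, -1])[:, None]
            return (-0.5 * np.log(2 * np.pi) - np.log(sig)
                    - 0.5 * ((y[None, :] - eta) / sig) ** 2)
        if self.family == "binomial":
            mm = np.ones_like(y) if m is None else m
            return (y[None, :] * eta - mm[None, :] * np.logaddexp(0.0, eta)
                    + (gammaln(mm + 1) - gammaln(y + 1)
                       - gammaln(mm - y + 1))[None, :])
        return y[None, :] * eta - np.exp(eta) - gammaln(y + 1)[None, :]


def _check_response(y, family, trials, allow_degenerate=False):
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if family == "binomial":
        m = np.ones_like(y) if trials is None else np.asarray(trials, float)
        if np.any((y < 0) | (y > m)):
            raise ValueError("binomial response outside [0, trials]")
        frac = y.sum() / m.sum()
        if frac in (0.0, 1.0) and not allow_degenerate:
            raise DegenerateFitError("constant binomial response")
    if family == "poisson":
        if np.any(y < 0):
            raise ValueError("negative count response")
        if np.all(y == 0):
            raise DegenerateFitError("all-zero count response")
    if family == "gaussian" and np.allclose(y, y[0]):
        raise DegenerateFitError("constant gaussian response")
    return y


def _nll_and_parts(eta, y, m, family, inv_var=1.0):
    """Negative log-likelihood, its eta-gradient and IRLS weights."""
    if family == "gaussian":
        r = y - eta
        nll = 0.5 * inv_var * float(r @ r)
        return nll, -r * inv_var, np.full_like(y, inv_var)
    if family == "binomial":
        mm = 1.0 if m is None else m
        nll = float(np.sum(mm * np.logaddexp(0.0, eta) - y * eta))
        p = expit(eta)
        return nll, mm * p - y, np.maximum(mm * p * (1.0 - p), 1e-10)
    mu = np.exp(np.clip(eta, -700, 700))
    nll = float(np.sum(mu - y * eta))
    return nll, mu - y, np.maximum(mu, 1e-10)


def _newton_map(X, y, m, family, gidx, q, sigma_u, beta0, u0,
                prior_sd_beta, inv_var=1.0, max_iter=100):
    """Damped Newton for the penalized log-likelihood over (beta, u).

    `prior_sd_beta` may be a scalar or a length-p vector of prior SDs.
    """
    n, p = X.shape
    beta, u = beta0.copy(), u0.copy()
    inv_vb = 1.0 / np.broadcast_to(np.asarray(prior_sd_beta, float), (p,))**2
    inv_vu = 1.0 / sigma_u**2 if q else 0.0

    def objective(beta, u):
        eta = X @ beta + (u[gidx] if q else 0.0)
        nll, dl, w = _nll_and_parts(eta, y, m, family, inv_var)
        pen = 0.5 * float(beta @ (inv_vb * beta))
        if q:
            pen += 0.5 * inv_vu * float(u @ u)
        return nll + pen, dl, w

    f, dl, w = objective(beta, u)
    for _ in range(max_iter):
        g_beta = X.T @ dl + inv_vb * beta
        Hbb = (X.T * w) @ X + np.diag(inv_vb)
        if q:
            g_u = np.bincount(gidx, weights=dl, minlength=q) + inv_vu * u
            wj = np.bincount(gidx, weights=w, minlength=q)
            Hbu = np.zeros((p, q))
            np.add.at(Hbu.T, gidx, X * w[:, None])
            H = np.block([[Hbb, Hbu],
                          [Hbu.T, np.diag(wj + inv_vu)]])
            g = np.concatenate([g_beta, g_u])
        else:
            H, g = Hbb, g_beta
        if np.max(np.abs(g)) < 1e-9 * max(1.0, n):
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ in range(40):
            nb = beta - t * step[:p]
            nu = u - t * step[p:] if q else u
            fn, dln, wn = objective(nb, nu)
            if fn <= f + 1e-12:
                break
            t *= 0.5
        else:
            break
        moved = t * float(np.max(np.abs(step)))
        beta, u, f, dl, w = nb, nu, fn, dln, wn
        if moved < 1e-12:
            break
    return beta, u, f, dl, w


def fit_glmm_laplace(
    X: np.ndarray,
    y,
    family: str,
    groups=None,
    trials=None,
    n_draws: int = 1000,
    seed: int = 0,
    prior_sd_beta: float = PRIOR_SD_BETA,
    allow_degenerate: bool = False,
) -> LaplaceFit:
    X = np.asarray(X, dtype=float)
    y = _check_response(y, family, trials, allow_degenerate)
    n, p = X.shape
    m = None if trials is None else np.asarray(trials, dtype=float)

    if groups is not None:
        labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
        q = len(labels)
    else:
        labels, gidx, q = (), None, 0

    beta = np.zeros(p)
    u = np.zeros(q)
    sigma_u = 0.3
    sigma_e = float(np.std(y)) if family == "gaussian" else None
    if sigma_e is not None:
        sigma_e = max(sigma_e, 1e-6)

    for _ in range(60):
        inv_var = 1.0 / sigma_e**2 if family == "gaussian" else 1.0
        beta, u, f, dl, w = _newton_map(X, y, m, family, gidx, q,
                                        max(sigma_u, SIGMA_U_FLOOR),
                                        beta, u, prior_sd_beta, inv_var)
        changed = False
        if family == "gaussian":
            eta = X @ beta + (u[gidx] if q else 0.0)
            new_sig = max(float(np.sqrt(np.mean((y - eta) ** 2))), 1e-8)
            changed |= abs(np.log(new_sig / sigma_e)) > 1e-8
            sigma_e = new_sig
        if q:
            # EM update with Laplace posterior variance of each u_j
            wj = np.bincount(gidx, weights=w, minlength=q)
            var_j = 1.0 / (wj + 1.0 / max(sigma_u, SIGMA_U_FLOOR) ** 2)
            new_su = float(np.sqrt(np.mean(u**2 + var_j)))
            new_su = max(new_su, SIGMA_U_FLOOR)
            changed |= abs(np.log(new_su / max(sigma_u, SIGMA_U_FLOOR))) > 1e-8
            sigma_u = new_su
        if not changed:
            break

    # final Hessian over (beta, u[, log sigma_e]) for the Laplace posterior
    inv_vb = 1.0 / np.broadcast_to(np.asarray(prior_sd_beta, float), (p,))**2
    inv_vu = 1.0 / max(sigma_u, SIGMA_U_FLOOR) ** 2
    eta = X @ beta + (u[gidx] if q else 0.0)
    inv_var = 1.0 / sigma_e**2 if family == "gaussian" else 1.0
    _, dl, w = _nll_and_parts(eta, y, m, family, inv_var)
    Hbb = (X.T * w) @ X + np.diag(inv_vb)
    blocks = [Hbb]
    if q:
        wj = np.bincount(gidx, weights=w, minlength=q)
        Hbu = np.zeros((p, q))
        np.add.at(Hbu.T, gidx, X * w[:, None])
        H = np.block([[Hbb, Hbu], [Hbu.T, np.diag(wj + inv_vu)]])
    else:
        H = Hbb
    mode = np.concatenate([beta, u])
    if family == "gaussian":
        r = y - eta
        hb = 2.0 * inv_var * (X.T @ r)
        hu = (2.0 * inv_var * np.bincount(gidx, weights=r, minlength=q)
              if q else np.zeros(0))
        hbb = 2.0 * inv_var * float(r @ r)
        top = np.concatenate([hb, hu])
        H = np.block([[H, top[:, None]], [top[None, :], np.array([[hbb]])]])
        mode = np.append(mode, np.log(sigma_e))

    cov = _safe_inverse(H)
    rng = np.random.default_rng(seed)
    draws = (rng.multivariate_normal(mode, cov, size=n_draws, method="cholesky")
             if n_draws > 0 else np.empty((0, len(mode))))
    return LaplaceFit(
        family=family,
        beta=beta.copy(),
        u=u.copy(),
        group_labels=tuple(labels),
        sigma_group=float(sigma_u) if q else 0.0,
        sigma_resid=float(sigma_e) if family == "gaussian" else None,
        mode=mode,
        cov=cov,
        draws=draws,
        n_obs=n,
        _X=X, _y=y, _trials=m, _group_idx=gidx,
    )


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (H + H.T))
    vals = np.clip(vals, 1e-10, None)
    return (vecs / vals) @ vecs.T
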