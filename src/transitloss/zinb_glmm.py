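"""Zero-inflated negative binomial mixed model for weekly condemnation counts.

The response is the weekly count of "dead" condemnations at one plant for
one swine class, with the log of total head slaughtered as an offset so the
model is a per-head rate model.  Fixed effects are cell means over swine
class crossed with exposure category (each class's baseline is its own
reference), the zero-inflation part is an intercept-only logit shared by
all rows, and a Gaussian random intercept on the five-level processing
volume category enters the count part only.

Count part (NB2):  Y | u ~ ZINB(mu, theta, pi),
    mu = exp(x'beta + log N + u),   Var(Y|u, not zero-inflated) = mu + mu^2/theta
Random effect:     u_g ~ Normal(0, sigma_u^2), one per volume category.

Estimation maximizes the exact marginal likelihood

    prod_g  ∫ prod_{i in g} P(y_i | u) phi(u; 0, sigma_u^2) du

with the integral evaluated by adaptive Gauss–Hermite quadrature: the
integrand is re-centred at its mode (found by a damped Newton search with
analytic derivatives) and rescaled by its curvature before the quadrature
rule is applied.  ``quad_points=1`` is exactly the Laplace approximation.
Optimization is quasi-Newton (L-BFGS-B) on the transformed scale
(beta, log theta, logit pi, log sigma_u); the Wald covariance comes from a
finite-difference Hessian of the negative marginal log-likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

__all__ = [
    "ModelSpec",
    "ZinbFit",
    "zinb_pmf",
    "zinb_logpmf",
    "zinb_rvs",
    "fit_zinb_glmm",
    "predict_rate",
]


@dataclass(frozen=True)
class ModelSpec:
    """Column mapping and design for the condemnation-count model.

    ``fixed`` names the categorical columns whose observed crossing defines
    the cell-means design (one indicator per cell, no global intercept).
    """

    response: str = "condemned"
    total: str = "total"
    fixed: tuple[str, ...] = ("swine_class", "category")
    group: str = "volume_category"


@dataclass
class ZinbFit:
    beta: np.ndarray
    beta_names: list
    theta: float
    pi: float
    sigma_u: float
    u_hat: dict
    vcov_beta: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    spec: ModelSpec
    message: str = ""
    quad_points: int = 15
    se_beta: np.ndarray = field(default=None)

    def coef(self, cell) -> float:
        return float(self.beta[self._idx(cell)])

    def _idx(self, cell) -> int:
        cell = _as_cell(cell)
        try:
            return self.beta_names.index(cell)
        except ValueError:
            raise KeyError(f"no coefficient for cell {cell!r}") from None

    def log_rr_se(self, cell_exposed, cell_baseline) -> float:
        """Delta-method SE of log(CR_exposed / CR_baseline).

        With cell-means coding and a shared zero-part, the log risk ratio is
        exactly beta_exposed - beta_baseline.
        """
        i, j = self._idx(cell_exposed), self._idx(cell_baseline)
        v = self.vcov_beta
        return float(np.sqrt(max(v[i, i] + v[j, j] - 2 * v[i, j], 0.0)))

    def to_dict(self) -> dict:
        return {
            "beta": {"/".join(map(str, n)): float(b)
                     for n, b in zip(self.beta_names, self.beta)},
            "se_beta": {"/".join(map(str, n)): float(s)
                        for n, s in zip(self.beta_names, self.se_beta)},
            "theta": self.theta,
            "pi": self.pi,
            "sigma_u": self.sigma_u,
            "u_hat": {str(k): float(v) for k, v in self.u_hat.items()},
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "quad_points": self.quad_points,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            "Zero-inflated negative binomial mixed model",
            f"  observations: {self.n_obs}   log-likelihood: {self.loglik:.3f}",
            f"  theta (NB dispersion): {self.theta:.4f}",
            f"  pi (zero inflation):   {self.pi:.4f}",
            f"  sigma_u (random int.): {self.sigma_u:.4f}",
            f"  converged: {self.converged}  {self.message}",
            "  coefficients (log per-head rate):",
        ]
        for n, b, s in zip(self.beta_names, self.beta, self.se_beta):
            lines.append(f"    {'/'.join(map(str, n)):28s} {b:10.4f}  (SE {s:.4f})")
        return "\n".join(lines)


def _as_cell(cell):
    if isinstance(cell, tuple):
        return cell
    return (cell,)


def _check_zinb_params(mu, theta, pi):
    if np.any(np.asarray(mu) <= 0):
        raise ValueError("mu must be positive")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if not 0.0 <= pi < 1.0:
        raise ValueError("pi must lie in [0, 1)")


def zinb_logpmf(y, mu, theta, pi):
    """Log pmf of the ZINB distribution (NB2 parameterization), vectorised."""
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    _check_zinb_params(mu, theta, pi)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    yf = y.astype(float)
    log_nb = (
        gammaln(yf + theta)
        - gammaln(theta)
        - gammaln(yf + 1.0)
        + theta * np.log(theta)
        + yf * np.log(mu)
        - (yf + theta) * np.log(theta + mu)
    )
    if pi == 0.0:
        return log_nb
    log1m = np.log1p(-pi)
    out = log1m + log_nb
    zero = y == 0
    if np.any(zero):
        log_q0 = theta * (np.log(theta) - np.log(theta + mu))
        with np.errstate(over="ignore"):
            out = np.where(
                zero, np.logaddexp(np.log(pi), log1m + np.broadcast_to(log_q0, out.shape)), out
            )
    return out


def zinb_pmf(y, mu, theta, pi):
    """ZINB probability mass: P(0) = pi + (1-pi) NB(0), P(y>0) = (1-pi) NB(y)."""
    return np.exp(zinb_logpmf(y, mu, theta, pi))


def zinb_rvs(mu, theta, pi, rng: np.random.Generator):
    """Draw ZINB variates; structural zeros with probability pi."""
    mu = np.asarray(mu, dtype=float)
    _check_zinb_params(mu, theta, pi)
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    if pi > 0:
        counts = np.where(rng.random(mu.shape) < pi, 0, counts)
    return counts


# ---------------------------------------------------------------------------
# marginal likelihood machinery


class _Design:
    """Pre-extracted arrays for fast repeated likelihood evaluation."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        y = np.asarray(data[spec.response])
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("response must be non-negative integers")
        total = np.asarray(data[spec.total], dtype=float)
        if np.any(total < 1):
            raise ValueError("every row needs total >= 1")
        self.y = y.astype(np.int64)
        self.log_n = np.log(total)
        cells = list(zip(*(data[c] for c in spec.fixed)))
        self.cell_names = sorted(set(cells))
        cell_pos = {c: i for i, c in enumerate(self.cell_names)}
        self.cell_idx = np.fromiter((cell_pos[c] for c in cells), dtype=np.int64)
        groups = np.asarray(data[spec.group])
        self.group_names = sorted(set(groups))
        if len(self.group_names) < 2:
            raise ValueError("need at least 2 random-effect groups")
        self.group_rows = [np.flatnonzero(groups == g) for g in self.group_names]
        # per-row constants reused across evaluations
        self.uy, self.inv_y = np.unique(self.y, return_inverse=True)
        self.lgam_y1 = gammaln(self.y + 1.0)
        self.is_pos = self.y > 0
        self.n = self.y.size
        self.p = len(self.cell_names)


def _group_loglik(y, eta, theta, pi, sigma, z, w, u0):
    """Adaptive GH marginal log-likelihood of one group; returns (ll, u_hat).

    ``eta`` is x'beta + log N for the group's rows; the integrand mode is
    found by damped Newton with analytic u-derivatives (no gammaln needed),
    then the rule centred at the mode. Constant-in-u pmf terms are added by
    the caller.
    """
    yf = y.astype(float)
    pos = y > 0
    log1m = np.log1p(-pi) if pi > 0 else 0.0
    lpi = np.log(pi) if pi > 0 else -np.inf

    def parts(u):
        # returns (f, f', f'') of the u-varying part of the joint log density
        mu = np.exp(eta + u)
        r = mu / (theta + mu)
        s = theta * r
        # y > 0 rows
        f = np.where(pos, yf * (eta + u) - (yf + theta) * np.log(theta + mu), 0.0)
        d1 = np.where(pos, yf - (yf + theta) * r, 0.0)
        d2 = np.where(pos, -(yf + theta) * theta * mu / (theta + mu) ** 2, 0.0)
        # y == 0 rows: log(pi + (1-pi) q), q = (theta/(theta+mu))^theta
        nz = ~pos
        if np.any(nz):
            log_q = theta * (np.log(theta) - np.log(theta + mu))
            if pi > 0:
                l0 = np.logaddexp(lpi, log1m + log_q)
                a = np.exp(log1m + log_q - l0)  # (1-pi) q / p0 in (0,1]
            else:
                l0 = log_q
                a = np.ones_like(log_q)
            g1 = -a * s
            # d2 of log p0: a*(s^2 - s') - (a*s)^2 with s' = s*theta/(theta+mu)
            sp = s * theta / (theta + mu)
            g2 = a * (s * s - sp) - (a * s) ** 2
            f = np.where(nz, l0, f)
            d1 = np.where(nz, g1, d1)
            d2 = np.where(nz, g2, d2)
        F = f.sum() - 0.5 * u * u / (sigma * sigma)
        D1 = d1.sum() - u / (sigma * sigma)
        D2 = d2.sum() - 1.0 / (sigma * sigma)
        return F, D1, D2

    u = float(u0)
    F, D1, D2 = parts(u)
    for _ in range(60):
        step = -D1 / min(D2, -1e-12)
        step = np.clip(step, -2.0, 2.0)
        for _ in range(25):
            Fn, D1n, D2n = parts(u + step)
            if Fn >= F - 1e-12:
                break
            step *= 0.5
        u += step
        F, D1, D2 = Fn, D1n, D2n
        if abs(step) < 1e-11:
            break
    h = max(-D2, 1e-10)
    scale = np.sqrt(2.0 / h)
    if z.size == 1:
        # Laplace approximation
        ll = F + 0.5 * np.log(2.0 * np.pi / h)
    else:
        nodes = u + scale * z
        fvals = np.array([parts(un)[0] for un in nodes])
        ll = logsumexp(np.log(w) + z * z + fvals) + np.log(scale)
    return ll, u


def _negloglik(params, d: _Design, quad, mode_cache):
    p = d.p
    beta = params[:p]
    theta = np.exp(params[p])
    pi = expit(params[p + 1])
    sigma = np.exp(params[p + 2])
    z, w = quad
    eta = beta[d.cell_idx] + d.log_n
    # u-invariant pmf pieces: gammaln terms, theta^theta, (1-pi) for y>0
    lg = gammaln(d.uy + theta)[d.inv_y] - gammaln(theta) - d.lgam_y1
    const = np.where(d.is_pos, lg + theta * np.log(theta), 0.0).sum()
    if pi > 0:
        const += np.log1p(-pi) * int(d.is_pos.sum())
    ll = const
    for gi, rows in enumerate(d.group_rows):
        gll, u_hat = _group_loglik(
            d.y[rows], eta[rows], theta, pi, sigma, z, w, mode_cache[gi]
        )
        mode_cache[gi] = u_hat
        ll += gll
    # normal prior normalization is inside _group_loglik up to -log(sigma*sqrt(2pi))
    ll -= len(d.group_rows) * (np.log(sigma) + 0.5 * np.log(2.0 * np.pi))
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _negloglik_grad(params, d: _Design, quad, mode_cache):
    """Negative marginal log-likelihood and its analytic gradient.

    The score uses Fisher's identity: the gradient of each group's marginal
    log-likelihood is the posterior expectation of the complete-data score,
    evaluated with the same adaptive Gauss–Hermite rule (posterior weights
    at the re-centred nodes).
    """
    from scipy.special import digamma

    p = d.p
    beta = params[:p]
    theta = np.exp(params[p])
    pi = expit(params[p + 1])
    sigma = np.exp(params[p + 2])
    z, w = quad
    eta = beta[d.cell_idx] + d.log_n

    lg = gammaln(d.uy + theta)[d.inv_y] - gammaln(theta) - d.lgam_y1
    n_pos = int(d.is_pos.sum())
    const = np.where(d.is_pos, lg + theta * np.log(theta), 0.0).sum()
    if pi > 0:
        const += np.log1p(-pi) * n_pos
    # u-invariant score pieces (y > 0 rows)
    dig = digamma(d.uy + theta)[d.inv_y] - digamma(theta)
    dtheta_const = float(np.where(d.is_pos, dig + np.log(theta) + 1.0, 0.0).sum())
    dpi_const = -n_pos / (1.0 - pi)

    ll = const
    grad = np.zeros(p + 3)
    grad[p] += dtheta_const
    grad[p + 1] += dpi_const
    log1m = np.log1p(-pi) if pi > 0 else 0.0
    lpi = np.log(pi) if pi > 0 else -np.inf

    for gi, rows in enumerate(d.group_rows):
        y = d.y[rows]
        yf = y.astype(float)
        pos = y > 0
        nz = ~pos
        eta_g = eta[rows]
        cell_g = d.cell_idx[rows]
        gll, u_hat = _group_loglik(
            y, eta_g, theta, pi, sigma, z, w, mode_cache[gi]
        )
        mode_cache[gi] = u_hat
        ll += gll
        # curvature at the mode for the node scale (recompute cheaply)
        _, _, D2 = _parts_fd(y, eta_g, theta, pi, sigma, u_hat)
        h = max(-D2, 1e-10)
        scale = np.sqrt(2.0 / h)
        nodes = u_hat + scale * z if z.size > 1 else np.array([u_hat])
        fvals = np.empty(nodes.size)
        dbeta_nodes = np.zeros((nodes.size, p))
        dtheta_nodes = np.empty(nodes.size)
        dpi_nodes = np.empty(nodes.size)
        dsig_nodes = np.empty(nodes.size)
        for j, u in enumerate(nodes):
            mu = np.exp(eta_g + u)
            r = mu / (theta + mu)
            s = theta * r
            f = np.where(pos, yf * (eta_g + u) - (yf + theta) * np.log(theta + mu), 0.0)
            db = np.where(pos, yf - (yf + theta) * r, 0.0)
            dt = np.where(pos, -np.log(theta + mu) - (yf + theta) / (theta + mu), 0.0)
            dp = np.zeros_like(f)
            if np.any(nz):
                log_q = theta * (np.log(theta) - np.log(theta + mu))
                if pi > 0:
                    l0 = np.logaddexp(lpi, log1m + log_q)
                    a = np.exp(log1m + log_q - l0)
                    q = np.exp(log_q)
                    p0 = np.exp(l0)
                    dp0 = (1.0 - q) / p0
                else:
                    l0 = log_q
                    a = np.ones_like(log_q)
                    dp0 = np.zeros_like(log_q)
                c = np.log(theta) - np.log(theta + mu) + r
                f = np.where(nz, l0, f)
                db = np.where(nz, -a * s, db)
                dt = np.where(nz, a * c, dt)
                dp = np.where(nz, dp0, dp)
            fvals[j] = f.sum() - 0.5 * u * u / (sigma * sigma)
            dbeta_nodes[j] = np.bincount(cell_g, weights=db, minlength=p)
            dtheta_nodes[j] = dt.sum()
            dpi_nodes[j] = dp.sum()
            dsig_nodes[j] = u * u / sigma**3
        if z.size == 1:
            omega = np.array([1.0])
        else:
            lw = np.log(w) + z * z + fvals
            omega = np.exp(lw - logsumexp(lw))
        grad[:p] += omega @ dbeta_nodes
        grad[p] += float(omega @ dtheta_nodes)
        grad[p + 1] += float(omega @ dpi_nodes)
        grad[p + 2] += float(omega @ dsig_nodes)

    ll -= len(d.group_rows) * (np.log(sigma) + 0.5 * np.log(2.0 * np.pi))
    grad[p + 2] -= len(d.group_rows) / sigma
    # chain rule to the transformed scale (log theta, logit pi, log sigma)
    grad[p] *= theta
    grad[p + 1] *= pi * (1.0 - pi)
    grad[p + 2] *= sigma
    if not np.isfinite(ll):
        return 1e12, np.zeros(p + 3)
    return -ll, -grad


def _parts_fd(y, eta, theta, pi, sigma, u):
    """(f, f', f'') of one group's joint log density at scalar u."""
    yf = y.astype(float)
    pos = y > 0
    mu = np.exp(eta + u)
    r = mu / (theta + mu)
    s = theta * r
    f = np.where(pos, yf * (eta + u) - (yf + theta) * np.log(theta + mu), 0.0)
    d1 = np.where(pos, yf - (yf + theta) * r, 0.0)
    d2 = np.where(pos, -(yf + theta) * theta * mu / (theta + mu) ** 2, 0.0)
    nz = ~pos
    if np.any(nz):
        log_q = theta * (np.log(theta) - np.log(theta + mu))
        if pi > 0:
            l0 = np.logaddexp(np.log(pi), np.log1p(-pi) + log_q)
            a = np.exp(np.log1p(-pi) + log_q - l0)
        else:
            l0 = log_q
            a = np.ones_like(log_q)
        sp = s * theta / (theta + mu)
        f = np.where(nz, l0, f)
        d1 = np.where(nz, -a * s, d1)
        d2 = np.where(nz, a * (s * s - sp) - (a * s) ** 2, d2)
    F = f.sum() - 0.5 * u * u / (sigma * sigma)
    D1 = d1.sum() - u / (sigma * sigma)
    D2 = d2.sum() - 1.0 / (sigma * sigma)
    return F, D1, D2


def _numeric_hessian(grad_fun, x, h=1e-5):
    """Hessian by central differences of the analytic gradient (2n evals)."""
    n = x.size
    step = h * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = step[i]
        H[i] = (grad_fun(x + e) - grad_fun(x - e)) / (2.0 * step[i])
    return (H + H.T) / 2.0


def fit_zinb_glmm(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    quad_points: int = 15,
    compute_vcov: bool = True,
) -> ZinbFit:
    """Fit the ZINB mixed model by direct marginal-likelihood maximization.

    ``quad_points`` controls the adaptive Gauss–Hermite rule (1 = Laplace).
    Non-convergence triggers up to three restarts from jittered starting
    values (fixed seeds); a fit that still fails is returned flagged, never
    silently.
    """
    d = _Design(data, spec)
    if quad_points < 1:
        raise ValueError("quad_points must be >= 1")
    if quad_points == 1:
        quad = (np.array([0.0]), np.array([np.sqrt(np.pi)]))
    else:
        quad = np.polynomial.hermite.hermgauss(quad_points)

    # starting values from a per-cell Poisson rate with a crude zero split
    p0_obs = float(np.mean(d.y == 0))
    pi0 = min(max(p0_obs - 0.2, 0.05), 0.8)
    rate = np.zeros(d.p)
    for i in range(d.p):
        rows = d.cell_idx == i
        rate[i] = (d.y[rows].sum() + 0.5) / np.exp(d.log_n[rows]).sum()
    beta0 = np.log(rate / (1.0 - pi0))
    x0 = np.concatenate([beta0, [np.log(1.0), np.log(pi0 / (1 - pi0)), np.log(0.2)]])
    bounds = [(-30.0, 10.0)] * d.p + [(-8.0, 12.0), (-12.0, 8.0), (-8.0, 3.0)]

    mode_cache = np.zeros(len(d.group_rows))
    obj = lambda x: _negloglik_grad(x, d, quad, mode_cache)

    best = None
    rng = np.random.default_rng(20100104)
    start = x0
    message = ""
    for attempt in range(4):
        res = minimize(
            obj,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            message = res.message if isinstance(res.message, str) else ""
            break
        start = x0 + rng.normal(scale=0.25, size=x0.size)
        message = f"restarted after: {res.message}"
    res = best
    x = res.x
    p = d.p
    theta = float(np.exp(x[p]))
    pi = float(expit(x[p + 1]))
    sigma = float(np.exp(x[p + 2]))

    if compute_vcov:
        H = _numeric_hessian(lambda v: obj(v)[1], x)
        try:
            cov = np.linalg.pinv((H + H.T) / 2.0)
        except np.linalg.LinAlgError:
            cov = np.full((x.size, x.size), np.nan)
        vcov_beta = (cov[:p, :p] + cov[:p, :p].T) / 2.0
        # clip tiny negative eigenvalues from finite differencing
        evals, evecs = np.linalg.eigh(vcov_beta)
        vcov_beta = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
    else:
        vcov_beta = np.full((p, p), np.nan)

    # final per-group modes
    u_hat = {}
    eta = x[:p][d.cell_idx] + d.log_n
    cache = mode_cache.copy()
    for gi, rows in enumerate(d.group_rows):
        _, uh = _group_loglik(d.y[rows], eta[rows], theta, pi, sigma,
                              quad[0], quad[1], cache[gi])
        u_hat[d.group_names[gi]] = float(uh)

    return ZinbFit(
        beta=x[:p].copy(),
        beta_names=[_as_cell(c) for c in d.cell_names],
        theta=theta,
        pi=pi,
        sigma_u=sigma,
        u_hat=u_hat,
        vcov_beta=vcov_beta,
        se_beta=np.sqrt(np.clip(np.diag(vcov_beta), 0.0, None)),
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_obs=d.n,
        spec=spec,
        message=str(message),
        quad_points=quad_points,
    )


def marginal_loglik(
    data: pd.DataFrame, fit: ZinbFit, quad_points: int | None = None
) -> float:
    """Marginal log-likelihood of ``data`` at a fit's parameters.

    Useful for quadrature self-consistency checks (re-evaluating the same
    fit under a finer Gauss–Hermite rule).
    """
    d = _Design(data, fit.spec)
    if d.cell_names != [tuple(n) for n in map(_as_cell, fit.beta_names)]:
        beta = np.array([fit.coef(c) for c in d.cell_names])
    else:
        beta = fit.beta
    q = quad_points or fit.quad_points
    quad = (
        (np.array([0.0]), np.array([np.sqrt(np.pi)]))
        if q == 1
        else np.polynomial.hermite.hermgauss(q)
    )
    params = np.concatenate(
        [
            beta,
            [np.log(fit.theta), np.log(fit.pi / (1 - fit.pi)) if fit.pi > 0 else -30.0,
             np.log(max(fit.sigma_u, 1e-8))],
        ]
    )
    return -_negloglik(params, d, quad, np.zeros(len(d.group_rows)))


def predict_rate(fit: ZinbFit, swine_class, category=None) -> float:
    """Population-level condemnation rate per head for one design cell.

    CR = (1 - pi) * exp(beta_cell) with the random effect at zero and the
    offset removed (per-head scale).  This is the marginal per-head rate up
    to the Poisson-thinning approximation of treating the weekly count rate
    as a per-head probability.
    """
    if not fit.converged:
        raise RuntimeError("model fit did not converge; refusing to predict")
    cell = (swine_class,) if category is None else (swine_class, category)
    return (1.0 - fit.pi) * float(np.exp(fit.coef(cell)))
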