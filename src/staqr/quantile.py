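"""Check-loss machinery and the asymmetric Laplace distribution.

The conditional theta-quantile minimises the expected check (pinball)
loss rho_theta(u) = u * (theta - 1{u < 0}). Maximising an asymmetric
Laplace (AL) likelihood with fixed skewness theta is equivalent to
minimising this loss, which is what lets a Bayesian sampler target
quantiles. A frequentist linear-programming fit is provided as the
reference solution for linear quantile regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

log = logging.getLogger(__name__)


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not 0.0 < theta < 1.0:
        raise ValueError(f"quantile level must lie in (0, 1), got {theta}")
    return theta


def mixture_constants(theta: float) -> tuple[float, float]:
    """Scale-mixture constants (xi, omega2) of the AL distribution.

    xi = (1 - 2 theta) / (theta (1 - theta)), omega2 = 2 / (theta (1 - theta)).
    With W ~ Exp(1) and V ~ N(0,1), sigma * (xi W + sqrt(omega2 W) V)
    is AL(0, sigma, theta).
    """
    theta = _check_theta(theta)
    denom = theta * (1.0 - theta)
    return (1.0 - 2.0 * theta) / denom, 2.0 / denom


@dataclass(frozen=True)
class ALParams:
    """Asymmetric Laplace parameters: location mu (the predictor),
    unit-free scale sigma > 0 and asymmetry theta in (0, 1)."""

    mu: float
    sigma: float
    theta: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("AL scale must be positive")
        _check_theta(self.theta)

    @property
    def xi(self) -> float:
        return mixture_constants(self.theta)[0]

    @property
    def omega2(self) -> float:
        return mixture_constants(self.theta)[1]


def check_loss(u, theta: float):
    """Pinball loss rho_theta(u): u*theta for u >= 0, u*(theta-1) for u < 0."""
    theta = _check_theta(theta)
    u = np.asarray(u, dtype=float)
    out = np.where(u >= 0.0, u * theta, u * (theta - 1.0))
    return out if out.ndim else float(out)

def total_loss(y, eta, theta: float) -> float:
    """Sum of check losses of the residuals y - eta."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {eta.shape}")
    return float(np.sum(check_loss(y - eta, theta)))


def al_logpdf(y, params: ALParams):
    """Log density of AL(mu, sigma, theta):
    log(theta (1-theta) / sigma) - rho_theta((y - mu) / sigma)."""
    th, s = params.theta, params.sigma
    y = np.asarray(y, dtype=float)
    out = np.log(th * (1.0 - th) / s) - check_loss((y - params.mu) / s, th)
    return out if out.ndim else float(out)


def fit_linear_qr(X, y, theta: float, method: str = "lp",
                  tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Frequentist linear quantile regression.

    Minimises ``sum_i rho_theta(y_i - x_i' beta)``. The default solver is
    the exact primal linear program with split positive/negative residuals
    (HiGHS); ``method="irls"`` runs iteratively reweighted least squares
    with a smoothing floor, converging to the same minimiser on
    non-degenerate problems.

    Returns the coefficient vector in the column order of ``X``.
    """
    theta = _check_theta(theta)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match rows of X")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    if method == "lp":
        # variables: [beta (free), u >= 0, v >= 0]; X beta + u - v = y
        c = np.concatenate([np.zeros(p), np.full(n, theta),
                            np.full(n, 1.0 - theta)])
        A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
        bounds = [(None, None)] * p + [(0, None)] * (2 * n)
        res = optimize.linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds,
                               method="highs")
        if not res.success:
            raise RuntimeError(f"LP quantile fit failed: {res.message}")
        beta = res.x[:p]
        n_zero = int(np.sum(np.abs(y - X @ beta) < 1e-9))
        if n_zero > p:
            log.info("quantile LP has %d interpolated points (> p=%d); "
                     "the solution may be non-unique", n_zero, p)
        return beta
    if method == "irls":
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        for _ in range(max_iter):
            r = y - X @ beta
            w = np.where(r >= 0, theta, 1.0 - theta) / np.maximum(np.abs(r),
                                                                  tol)
            Xw = X * w[:, None]
            new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
            if np.max(np.abs(new - beta)) < tol:
                beta = new
                break
            beta = new
        return beta
    raise ValueError(f"unknown method {method!r}")


def sample_al(rng: np.random.Generator, size: int, mu: float = 0.0,
              sigma: float = 1.0, theta: float = 0.5) -> np.ndarray:
    """Draw from AL(mu, sigma, theta) via the normal-exponential mixture."""
    xi, om2 = mixture_constants(theta)
    w = rng.exponential(1.0, size)
    v = rng.standard_normal(size)
    return mu + sigma * (xi * w + np.sqrt(om2 * w) * v)
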