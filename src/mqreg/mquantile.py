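"""Asymmetric Huber loss machinery and single-level M-quantile regression.

An M-quantile of order ``q`` generalises the quantile through an asymmetric
influence function: with the Huber influence, the tuning constant ``c``
interpolates between expectile regression (large ``c``, asymmetric least
squares) and quantile regression (``c`` close to zero).  The single-level
fit here serves both as a standalone estimator for independent observations
and as the initialiser for the random-effects extension in
:mod:`mqreg.estimation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateScaleError,
    InvalidParameterError,
    SingularDesignError,
)

__all__ = [
    "MQSpec",
    "MQFit",
    "huber_psi",
    "asym_psi",
    "asym_rho",
    "mad_scale",
    "fit_mq",
]

#: Consistency constant making the MAD unbiased for the SD under normality.
MAD_CONSTANT = 0.6745


@dataclass(frozen=True)
class MQSpec:
    """Target location parameter of an M-quantile model.

    Parameters
    ----------
    q : float
        Quantile-like index, strictly inside (0, 1).  ``q=0.5`` targets the
        centre of the conditional distribution.
    c : float
        Huber tuning constant, strictly positive.  Small ``c`` buys
        robustness at the price of efficiency; ``c=1.345`` gives 95%
        Gaussian efficiency in location estimation.
    loss : {"huber", "squared"}
        Loss family.  ``"squared"`` is the expectile limit and behaves
        identically to ``"huber"`` with ``c`` at infinity.
    """

    q: float
    c: float = 1.345
    loss: str = "huber"

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise InvalidParameterError(f"q must lie in (0, 1), got {self.q}")
        if not self.c > 0.0:
            raise InvalidParameterError(f"c must be > 0, got {self.c}")
        if self.loss not in ("huber", "squared"):
            raise InvalidParameterError(
                f"loss must be 'huber' or 'squared', got {self.loss!r}"
            )


@dataclass
class MQFit:
    """Result of a single-level M-quantile regression fit."""

    spec: MQSpec
    beta: np.ndarray
    scale: float
    residuals: np.ndarray
    iterations: int
    converged: bool
    objective: float = field(default=np.nan)


def huber_psi(u, c):
    """Huber influence function ``psi(u) = u`` clipped to ``[-c, c]``.

    Odd, monotone and bounded by ``c`` in absolute value.
    """
    if not c > 0.0:
        raise InvalidParameterError(f"c must be > 0, got {c}")
    return np.clip(u, -c, c)


def _asym_weights(u, q):
    """q for positive arguments, 1-q otherwise (ties go to the left)."""
    return np.where(np.asarray(u, dtype=float) > 0.0, q, 1.0 - q)


def asym_psi(u, spec: MQSpec, s: float = 1.0):
    """Asymmetric influence ``psi_q(u) = 2 psi(u/s) {q or (1-q)}``.

    The asymmetry weight is ``q`` when the (raw) residual is positive and
    ``1-q`` otherwise; at ``q=0.5`` this reduces to the symmetric Huber
    ``psi`` applied to ``u/s``.
    """
    if not s > 0.0:
        raise InvalidParameterError(f"scale s must be > 0, got {s}")
    u = np.asarray(u, dtype=float)
    a = _asym_weights(u, spec.q)
    if spec.loss == "squared":
        core = u / s
    else:
        core = huber_psi(u / s, spec.c)
    return 2.0 * a * core


def asym_psi_deriv(u, spec: MQSpec):
    """Almost-everywhere derivative of :func:`asym_psi` (with ``s=1``).

    Equals ``2 {q or (1-q)}`` inside the Huber core and 0 beyond it.
    """
    u = np.asarray(u, dtype=float)
    a = _asym_weights(u, spec.q)
    if spec.loss == "squared":
        return 2.0 * a
    return 2.0 * a * (np.abs(u) <= spec.c)


def asym_rho(u, spec: MQSpec):
    """Asymmetric Huber loss: quadratic core, linear tails, tilted by q.

    Nonnegative, zero only at the origin, with derivative
    ``asym_psi(u, spec, s=1)``.
    """
    u = np.asarray(u, dtype=float)
    a = _asym_weights(u, spec.q)
    if spec.loss == "squared":
        return u**2 * a
    c = spec.c
    core = np.abs(u) <= c
    return np.where(core, u**2, 2.0 * c * np.abs(u) - c**2) * a


def mad_scale(residuals) -> float:
    """Median absolute deviation scale ``median|r| / 0.6745``.

    Normalised so that the estimate is consistent for the standard
    deviation under Gaussian residuals.
    """
    r = np.asarray(residuals, dtype=float)
    med = float(np.median(np.abs(r)))
    if med <= 0.0:
        raise DegenerateScaleError(
            "median absolute residual is zero; robust scale is degenerate"
        )
    return med / MAD_CONSTANT


def fit_mq(
    X,
    y,
    spec: MQSpec,
    *,
    tol: float = 1e-6,
    obj_tol: float = 1e-8,
    max_iter: int = 200,
) -> MQFit:
    """Fit a linear M-quantile regression by iterative weighted least squares.

    Solves the estimating equation ``sum_i psi_q(r_i) x_i = 0`` where
    ``psi_q`` applies the asymmetric Huber influence to residuals
    standardised by the MAD scale (re-estimated at each iteration).  With a
    monotone influence and ``c > 0`` the solution is unique, so the OLS
    start is immaterial.

    Parameters
    ----------
    X : array_like, shape (n, p)
        Full-column-rank design matrix (include the intercept explicitly).
    y : array_like, shape (n,)
        Response vector.
    spec : MQSpec
        Target M-quantile (q, c, loss family).
    tol, obj_tol, max_iter
        Convergence is declared when the max absolute coefficient change
        falls below ``tol`` and the relative objective change below
        ``obj_tol``.

    Returns
    -------
    MQFit
        Non-convergence within ``max_iter`` is flagged, never silent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise InvalidParameterError(f"need n > p, got n={n}, p={p}")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise SingularDesignError(
            f"design matrix has rank {rank} < {p} columns"
        )

    q = spec.q
    obj_prev = np.inf
    converged = False
    s = 1.0
    it = 0
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        s = mad_scale(r)
        u = r / s
        a = _asym_weights(u, q)
        if spec.loss == "squared":
            w = 2.0 * a
        else:
            # psi(u)/u with the continuity completion 1 at u = 0
            safe = np.where(u == 0.0, 1.0, u)
            w = 2.0 * a * np.where(u == 0.0, 1.0, huber_psi(u, spec.c) / safe)
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        obj = float(np.sum(asym_rho((y - X @ beta_new) / s, spec)))
        step = float(np.max(np.abs(beta_new - beta)))
        rel_obj = abs(obj - obj_prev) / (1.0 + abs(obj))
        beta = beta_new
        obj_prev = obj
        if step < tol and rel_obj < obj_tol:
            converged = True
            break

    r = y - X @ beta
    s = mad_scale(r)
    return MQFit(
        spec=spec,
        beta=beta,
        scale=s,
        residuals=r,
        iterations=it,
        converged=converged,
        objective=float(np.sum(asym_rho(r / s, spec))),
    )
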