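"""M-quantile random-effects regression for two-level data.

The model places a group-specific random intercept inside the linear
predictor of the order-q M-quantile,

    MQ_y(q | x, gamma_j) = x' beta_q + gamma_j,

and estimates ``beta_q`` together with the q-specific variance components
``(sigma2_gamma, sigma2_eps)`` from robustified estimating equations: the
asymmetric Huber influence ``psi_q`` is applied to residuals scaled by the
marginal standard deviation, and the variance-component equations are
recentred by the Gaussian calibration constant ``K2q = E[psi_q(eps)^2]``
with ``eps ~ N(0, 1)``.  Fixed effects are solved by damped Newton-Raphson,
variance components by a positivity-preserving fixed-point iteration; the
two are alternated until all three estimating equations are (numerically)
zero.  Special cases recovered exactly: q=0.5 with squared loss is Gaussian
ML for the random-intercepts model; q=0.5 with Huber loss is robust ML
("proposal II"); squared loss at q != 0.5 is expectile random-effects
regression.

Random effects are predicted from a modified Fellner equation in which the
same asymmetric influence bounds both the residual and the random-effect
contributions, yielding an outlier-resistant analogue of the BLUP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from .data import GroupedDataset
from .errors import (
    DataError,
    InvalidParameterError,
    NotConvergedError,
)
from .mquantile import MQSpec, asym_psi, asym_psi_deriv, fit_mq, mad_scale

__all__ = [
    "VarianceComponents",
    "K2Constant",
    "MQREFit",
    "MQREOptions",
    "compute_k2q",
    "build_covariance",
    "BlockCovariance",
    "scaled_residuals",
    "beta_step",
    "variance_step",
    "fit_mqre",
    "fit_expectile_re",
    "predict_random_effects",
]

#: Lower floor for variance components (boundary clamp).
VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class VarianceComponents:
    """Level-2 (group) and level-1 (occasion) variances of the model."""

    sigma2_gamma: float
    sigma2_eps: float

    def __post_init__(self) -> None:
        if not self.sigma2_eps > 0.0:
            raise InvalidParameterError(
                f"sigma2_eps must be > 0, got {self.sigma2_eps}"
            )
        if self.sigma2_gamma < 0.0:
            raise InvalidParameterError(
                f"sigma2_gamma must be >= 0, got {self.sigma2_gamma}"
            )

    @property
    def marginal_variance(self) -> float:
        """Diagonal of V: var(y_ij) = sigma2_eps + sigma2_gamma."""
        return self.sigma2_eps + self.sigma2_gamma


@dataclass(frozen=True)
class K2Constant:
    """Gaussian calibration constant for the variance estimating equations.

    ``value = E[psi_q(Z - m_q)^2]`` with ``Z ~ N(0, 1)`` and ``m_q`` the
    order-q M-quantile of the standard normal (``shift``), i.e. the root of
    ``E[psi_q(Z - m)] = 0``.  Centring the reference at its own M-quantile
    mirrors what the scaled residuals look like at the q-th solution and
    keeps the variance equations soluble at every q: the uncentred
    expectation exceeds the attainable supremum of the residual side once
    q moves far from 0.5.  At q = 0.5 the shift is 0 and the constant
    reduces to the symmetric form ``2A`` with
    ``A = Phi(c) - 1/2 - c phi(c) + c^2 (1 - Phi(c))``
    (0.7102 at c = 1.345; exactly 1 under squared loss).
    """

    q: float
    c: float
    loss: str
    value: float
    shift: float


def _normal_mquantile(q: float, c: float, loss: str) -> float:
    """Order-q M-quantile m of N(0,1): root of E[psi_q(Z - m)] = 0."""
    if np.isclose(q, 0.5):
        return 0.0

    def balance(m):
        if loss == "squared":
            # E[(Z-m) I(Z>m)] = phi(m) - m sf(m); E[(Z-m) I(Z<=m)] = -phi(m) - m Phi(m)
            pos = stats.norm.pdf(m) - m * stats.norm.sf(m)
            neg = -stats.norm.pdf(m) - m * stats.norm.cdf(m)
        else:
            pos = (
                stats.norm.pdf(m)
                - stats.norm.pdf(m + c)
                - m * (stats.norm.cdf(m + c) - stats.norm.cdf(m))
                + c * stats.norm.sf(m + c)
            )
            neg = (
                stats.norm.pdf(m - c)
                - stats.norm.pdf(m)
                - m * (stats.norm.cdf(m) - stats.norm.cdf(m - c))
                - c * stats.norm.cdf(m - c)
            )
        return 2.0 * (q * pos + (1.0 - q) * neg)

    from scipy.optimize import brentq

    return float(brentq(balance, -10.0, 10.0, xtol=1e-12))


def _truncated_sq_moment(a: float, b: float, m: float) -> float:
    """E[(Z - m)^2 I(a < Z <= b)] for Z ~ N(0, 1) (closed form)."""
    phi, Phi = stats.norm.pdf, stats.norm.cdf
    aphi = 0.0 if np.isinf(a) else a * phi(a)
    bphi = 0.0 if np.isinf(b) else b * phi(b)
    # integrals of z^2, z, 1 against phi on (a, b]
    i2 = Phi(b) - Phi(a) + aphi - bphi
    i1 = phi(a) - phi(b)
    i0 = Phi(b) - Phi(a)
    return i2 - 2.0 * m * i1 + m**2 * i0


@lru_cache(maxsize=256)
def _k2q_cached(q: float, c: float, loss: str) -> K2Constant:
    m = _normal_mquantile(q, c, loss)
    if loss == "squared":
        t_pos = _truncated_sq_moment(m, np.inf, m)
        t_neg = _truncated_sq_moment(-np.inf, m, m)
    else:
        t_pos = _truncated_sq_moment(m, m + c, m) + c**2 * stats.norm.sf(m + c)
        t_neg = _truncated_sq_moment(m - c, m, m) + c**2 * stats.norm.cdf(m - c)
    value = 4.0 * (q**2 * t_pos + (1.0 - q) ** 2 * t_neg)
    return K2Constant(q=q, c=c, loss=loss, value=float(value), shift=m)


def compute_k2q(q: float, c: float, loss: str = "huber") -> K2Constant:
    """Gaussian calibration constant ``E[psi_q(Z - m_q)^2]`` in closed form.

    Built from truncated normal moments; matches adaptive quadrature of
    ``int psi_q(z - m_q)^2 phi(z) dz`` to machine precision and is
    symmetric under q <-> 1-q.
    """
    spec = MQSpec(q=q, c=c, loss=loss)  # validates q, c, loss
    return _k2q_cached(spec.q, spec.c, spec.loss)


class BlockCovariance:
    """Block-diagonal covariance V = sigma2_eps I + sigma2_gamma Z Z'.

    For a random-intercepts model V decomposes into per-group blocks
    ``V_j = sigma2_eps I_{nj} + sigma2_gamma 1 1'`` whose inverse, trace
    and log-determinant follow from the rank-one (Sherman-Morrison)
    identity.  No n-by-n matrix is ever materialised: solves cost O(n)
    through per-group sums.
    """

    def __init__(self, vc: VarianceComponents, data: GroupedDataset) -> None:
        self.vc = vc
        self.data = data
        se2 = vc.sigma2_eps
        sg2 = vc.sigma2_gamma
        nj = data.group_sizes.astype(float)
        # Sherman-Morrison factor: V_j^{-1} = (I - rho_j 1 1') / sigma2_eps
        self._rho = sg2 / (se2 + nj * sg2)

    def solve(self, v: np.ndarray) -> np.ndarray:
        """V^{-1} v for an n-vector or (n, k) matrix."""
        d = self.data
        se2 = self.vc.sigma2_eps
        if v.ndim == 1:
            gs = d.group_sum(v)
            return (v - self._rho[d.group_idx] * gs[d.group_idx]) / se2
        out = np.empty_like(v, dtype=float)
        for k in range(v.shape[1]):
            out[:, k] = self.solve(v[:, k])
        return out

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """V v."""
        d = self.data
        gs = d.group_sum(v)
        return self.vc.sigma2_eps * v + self.vc.sigma2_gamma * gs[d.group_idx]

    def diagonal(self) -> np.ndarray:
        """diag(V) = (sigma2_eps + sigma2_gamma) 1 — the matrix U_q."""
        return np.full(self.data.n, self.vc.marginal_variance)

    def logdet(self) -> float:
        se2 = self.vc.sigma2_eps
        sg2 = self.vc.sigma2_gamma
        nj = self.data.group_sizes.astype(float)
        return float(
            np.sum((nj - 1.0) * np.log(se2) + np.log(se2 + nj * sg2))
        )

    def trace_inv(self) -> float:
        """tr(V^{-1})."""
        nj = self.data.group_sizes.astype(float)
        return float(np.sum(nj * (1.0 - self._rho) / self.vc.sigma2_eps))

    def trace_inv_zzt(self) -> float:
        """tr(V^{-1} Z Z') = sum_j 1' V_j^{-1} 1."""
        nj = self.data.group_sizes.astype(float)
        se2 = self.vc.sigma2_eps
        sg2 = self.vc.sigma2_gamma
        return float(np.sum(nj / (se2 + nj * sg2)))

    def group_one_dot_inv(self, v: np.ndarray) -> np.ndarray:
        """Length-d vector of 1' V_j^{-1} v_j (the Z' V^{-1} v contractions)."""
        return self.data.group_sum(self.solve(v))

    def block(self, j: int) -> np.ndarray:
        """Dense covariance block of group j (for inspection and testing)."""
        nj = int(self.data.group_sizes[j])
        return self.vc.sigma2_eps * np.eye(nj) + self.vc.sigma2_gamma * np.ones(
            (nj, nj)
        )


def build_covariance(vc: VarianceComponents, data: GroupedDataset) -> BlockCovariance:
    """Block covariance handle for V_q (inverse, traces, logdet, products)."""
    return BlockCovariance(vc, data)


def scaled_residuals(
    data: GroupedDataset, beta: np.ndarray, vc: VarianceComponents
) -> np.ndarray:
    """r_q = U_q^{-1/2} (y - X beta), with U_q = diag(V_q)."""
    su = np.sqrt(vc.marginal_variance)
    return (data.y - data.X @ beta) / su


@dataclass
class MQREOptions:
    """Solver controls for :func:`fit_mqre`.

    Outer convergence is the maximum relative parameter change across
    (beta, sigma2_gamma, sigma2_eps); the converged flag additionally
    requires all three estimating-equation norms below ``eq_tol_scale * n``.
    """

    outer_tol: float = 1e-6
    max_outer: int = 500
    inner_tol: float = 1e-9
    max_inner: int = 50
    eq_tol_scale: float = 1e-6
    var_floor: float = VAR_FLOOR


@dataclass
class MQREFit:
    """Fitted M-quantile random-effects model at one value of q."""

    spec: MQSpec
    beta: np.ndarray
    varcomp: VarianceComponents
    gamma: np.ndarray
    scaled_residuals: np.ndarray
    beta_cov: np.ndarray
    iterations: int
    converged: bool
    eq_norms: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    boundary_gamma: bool = False


def _score_beta(data, beta, vc, spec, cov=None):
    """Estimating-equation value X' V^{-1} U^{1/2} psi_q(r_q) and residual parts."""
    if cov is None:
        cov = BlockCovariance(vc, data)
    su = np.sqrt(vc.marginal_variance)
    r = (data.y - data.X @ beta) / su
    psi = asym_psi(r, spec)
    g = data.X.T @ cov.solve(su * psi)
    return g, r, psi, cov


def beta_step(
    data: GroupedDataset,
    beta: np.ndarray,
    vc: VarianceComponents,
    spec: MQSpec,
    *,
    max_halvings: int = 30,
):
    """One damped Newton-Raphson step for the fixed effects.

    The Jacobian of the score uses the a.e. derivative of ``psi_q``; the
    diagonal ``U^{1/2}``/``U^{-1/2}`` factors cancel because U is a scalar
    multiple of the identity for a random-intercepts model.  The step is
    halved until the score norm does not increase; a singular Jacobian is
    retried with a ridge.
    """
    g, r, _, cov = _score_beta(data, beta, vc, spec)
    gnorm = float(np.linalg.norm(g))
    if gnorm == 0.0:
        return beta, g
    dpsi = asym_psi_deriv(r, spec)
    J = data.X.T @ cov.solve(data.X * dpsi[:, None])
    try:
        delta = np.linalg.solve(J, g)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * (np.trace(J) / J.shape[0] + 1.0)
        delta = np.linalg.solve(J + ridge * np.eye(J.shape[0]), g)
    step = 1.0
    for _ in range(max_halvings):
        cand = beta + step * delta
        g_new, _, _, _ = _score_beta(data, cand, vc, spec, cov)
        if float(np.linalg.norm(g_new)) <= gnorm:
            return cand, g_new
        step *= 0.5
    # no decrease found: keep current point, caller sees stalled score
    return beta, g


def _solve_beta(data, beta, vc, spec, opts: MQREOptions):
    """Newton-Raphson to inner convergence (score sup-norm below tolerance)."""
    scale = 1.0 + float(np.abs(data.X).max()) * data.n
    for _ in range(opts.max_inner):
        beta_new, g = beta_step(data, beta, vc, spec)
        if float(np.max(np.abs(g))) < opts.inner_tol * scale:
            return beta_new
        if np.max(np.abs(beta_new - beta)) < 1e-14:
            return beta_new
        beta = beta_new
    return beta


def _variance_terms(data, beta, vc, spec, cov=None):
    """Quadratic forms and traces entering the two variance equations."""
    if cov is None:
        cov = BlockCovariance(vc, data)
    su = np.sqrt(vc.marginal_variance)
    r = (data.y - data.X @ beta) / su
    psi = asym_psi(r, spec)
    w = su * psi
    a = cov.solve(w)  # V^{-1} U^{1/2} psi
    t = data.group_sum(a)  # Z' V^{-1} U^{1/2} psi
    num_gamma = float(t @ t)
    num_eps = float(a @ a)
    return num_gamma, num_eps, cov.trace_inv_zzt(), cov.trace_inv()


def variance_step(
    data: GroupedDataset,
    beta: np.ndarray,
    vc: VarianceComponents,
    spec: MQSpec,
    k2: K2Constant | None = None,
    *,
    var_floor: float = VAR_FLOOR,
) -> VarianceComponents:
    """One multiplicative fixed-point update of both variance components.

    Each component is scaled by the ratio of the quadratic-form side to the
    calibrated trace side of its estimating equation, so positivity is
    preserved and a stationary point solves the equation exactly.  Updates
    falling below the floor are clamped (boundary estimate) with a warning.
    """
    if k2 is None:
        k2 = compute_k2q(spec.q, spec.c, spec.loss)
    num_g, num_e, tr_zzt, tr_inv = _variance_terms(data, beta, vc, spec)
    sg2 = vc.sigma2_gamma * num_g / (k2.value * tr_zzt)
    se2 = vc.sigma2_eps * num_e / (k2.value * tr_inv)
    if sg2 < var_floor:
        warnings.warn(
            "sigma2_gamma update hit the lower floor; boundary estimate",
            RuntimeWarning,
            stacklevel=2,
        )
        sg2 = var_floor
    if se2 < var_floor:
        warnings.warn(
            "sigma2_eps update hit the lower floor; boundary estimate",
            RuntimeWarning,
            stacklevel=2,
        )
        se2 = var_floor
    return VarianceComponents(sigma2_gamma=sg2, sigma2_eps=se2)


def _eq_norms(data, beta, vc, spec, k2):
    """Absolute values of the three estimating-equation left-hand sides."""
    g, _, _, cov = _score_beta(data, beta, vc, spec)
    num_g, num_e, tr_zzt, tr_inv = _variance_terms(data, beta, vc, spec, cov)
    eq_gamma = 0.5 * abs(num_g - k2.value * tr_zzt)
    eq_eps = 0.5 * abs(num_e - k2.value * tr_inv)
    return np.array([float(np.max(np.abs(g))), eq_gamma, eq_eps])


def _initial_state(data, spec):
    """Robust starting values: single-level MQ fit plus a moment split.

    sigma2_eps starts from the squared within-group MAD of the raw MQ
    residuals, sigma2_gamma from the between-group variance of group mean
    residuals; both floored away from zero.
    """
    mq = fit_mq(data.X, data.y, spec)
    resid = mq.residuals
    means = data.group_mean(resid)
    within = resid - means[data.group_idx]
    try:
        se2 = mad_scale(within) ** 2
    except Exception:
        se2 = float(np.var(within)) or 1.0
    sg2 = float(np.var(means, ddof=1)) if data.d > 1 else 0.0
    se2 = max(se2, VAR_FLOOR)
    sg2 = max(sg2, VAR_FLOOR)
    return mq.beta.copy(), VarianceComponents(sigma2_gamma=sg2, sigma2_eps=se2)


def fit_mqre(
    data: GroupedDataset,
    spec: MQSpec,
    opts: MQREOptions | None = None,
    *,
    fixed_varcomp: VarianceComponents | None = None,
    predict_effects: bool = True,
    compute_cov: bool = True,
) -> MQREFit:
    """Fit the M-quantile random-effects model at one value of q.

    Alternates a full Newton-Raphson solve for the fixed effects with one
    fixed-point sweep over the variance components until the maximum
    relative parameter change drops below ``opts.outer_tol``; the fit is
    declared converged only if, in addition, all three estimating-equation
    norms fall below ``opts.eq_tol_scale * n``.  Non-convergence returns a
    flagged fit with diagnostics rather than raising.

    Parameters
    ----------
    fixed_varcomp : VarianceComponents, optional
        Hold the variance components fixed at the given values (only the
        fixed effects are estimated).
    predict_effects, compute_cov : bool
        Skip the Fellner prediction / sandwich covariance for speed.
    """
    if data.d < 2 and fixed_varcomp is None:
        raise DataError("at least 2 groups are required to fit random effects")
    if data.n <= data.p:
        raise InvalidParameterError("need n > p")
    opts = opts or MQREOptions()
    k2 = compute_k2q(spec.q, spec.c, spec.loss)

    beta, vc = _initial_state(data, spec)
    if fixed_varcomp is not None:
        vc = fixed_varcomp

    it = 0
    param_converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("once", RuntimeWarning)
        for it in range(1, opts.max_outer + 1):
            beta_new = _solve_beta(data, beta, vc, spec, opts)
            if fixed_varcomp is None:
                vc_new = variance_step(
                    data, beta_new, vc, spec, k2, var_floor=opts.var_floor
                )
            else:
                vc_new = vc
            rel = max(
                float(
                    np.max(
                        np.abs(beta_new - beta) / (1.0 + np.abs(beta_new))
                    )
                ),
                abs(vc_new.sigma2_gamma - vc.sigma2_gamma)
                / (1.0 + vc_new.sigma2_gamma),
                abs(vc_new.sigma2_eps - vc.sigma2_eps)
                / (1.0 + vc_new.sigma2_eps),
            )
            beta, vc = beta_new, vc_new
            if rel < opts.outer_tol:
                param_converged = True
                break
        # re-solve beta at the final variance components
        beta = _solve_beta(data, beta, vc, spec, opts)

    eq = _eq_norms(data, beta, vc, spec, k2)
    eq_ok = bool(np.all(eq < opts.eq_tol_scale * data.n))
    if fixed_varcomp is not None:
        # only the beta equation is required to hold
        eq_ok = bool(eq[0] < opts.eq_tol_scale * data.n)
    converged = param_converged and eq_ok

    boundary = vc.sigma2_gamma <= opts.var_floor
    r = scaled_residuals(data, beta, vc)

    if predict_effects:
        gamma = _predict_gamma(data, beta, vc, spec, var_floor=opts.var_floor)
    else:
        gamma = np.zeros(data.d)

    if compute_cov:
        beta_cov = _beta_sandwich(data, beta, vc, spec)
    else:
        beta_cov = np.full((data.p, data.p), np.nan)

    return MQREFit(
        spec=spec,
        beta=beta,
        varcomp=vc,
        gamma=gamma,
        scaled_residuals=r,
        beta_cov=beta_cov,
        iterations=it,
        converged=converged,
        eq_norms=eq,
        boundary_gamma=boundary,
    )


def fit_expectile_re(
    data: GroupedDataset,
    q: float,
    opts: MQREOptions | None = None,
    **kwargs,
) -> MQREFit:
    """Expectile random-effects regression: squared loss at index q.

    At q = 0.5 this is exactly the Gaussian ML fit of the random-intercepts
    model.
    """
    # c is never applied under squared loss; a large finite value keeps repr sane
    spec = MQSpec(q=q, c=1e6, loss="squared")
    return fit_mqre(data, spec, opts, **kwargs)


def _predict_gamma(data, beta, vc, spec, *, var_floor=VAR_FLOOR, n_bisect=200):
    """Solve the modified Fellner equation for the random effects.

    The system decouples over groups into scalar equations

        (1/s_e) sum_i psi_q((e_ij - g)/s_e) - (1/s_g) psi_q(g/s_g) = 0,

    each monotone non-increasing in g, solved by vectorised bisection.
    With squared loss at q = 0.5 the root is the classical BLUP shrinkage
    of the group mean residual.
    """
    if vc.sigma2_gamma <= var_floor:
        return np.zeros(data.d)
    s_e = np.sqrt(vc.sigma2_eps)
    s_g = np.sqrt(vc.sigma2_gamma)
    e = data.y - data.X @ beta

    def f(g):
        term1 = data.group_sum(asym_psi((e - g[data.group_idx]) / s_e, spec)) / s_e
        term2 = asym_psi(g / s_g, spec) / s_g
        return term1 - term2

    bound = float(np.max(np.abs(e))) + 10.0 * (s_e + s_g)
    lo = np.full(data.d, -bound)
    hi = np.full(data.d, bound)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        pos = val > 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
        if np.max(hi - lo) < 1e-12 * bound:
            break
    return 0.5 * (lo + hi)


def predict_random_effects(fit: MQREFit, data: GroupedDataset) -> np.ndarray:
    """Predicted q-specific random effects from a converged fit."""
    if not fit.converged:
        raise NotConvergedError(
            "random-effect prediction requires a converged fit"
        )
    if fit.boundary_gamma:
        warnings.warn(
            "sigma2_gamma at its floor: random effects shrunk to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros(data.d)
    return _predict_gamma(data, fit.beta, fit.varcomp, fit.spec)


def _beta_sandwich(data, beta, vc, spec):
    """Taylor-linearisation (sandwich) covariance of the fixed effects.

    Bread: observed derivative of the score, A = X' V^{-1} diag(psi_q'(r)) X
    (diagonal U factors cancel).  Meat: cluster-level empirical outer
    product of group score contributions with a d/(d-1) degrees-of-freedom
    correction, capturing within-group score correlation.  Symmetric PSD by
    construction; variance-component uncertainty is not propagated
    (plug-in).
    """
    cov = BlockCovariance(vc, data)
    su = np.sqrt(vc.marginal_variance)
    r = (data.y - data.X @ beta) / su
    psi = asym_psi(r, spec)
    dpsi = asym_psi_deriv(r, spec)
    A = data.X.T @ cov.solve(data.X * dpsi[:, None])
    a = cov.solve(su * psi)
    G = np.zeros((data.d, data.p))
    np.add.at(G, data.group_idx, data.X * a[:, None])
    ddof = data.d / max(data.d - 1, 1)
    B = ddof * (G.T @ G)
    Ainv = np.linalg.inv(A)
    C = Ainv @ B @ Ainv.T
    return 0.5 * (C + C.T)


def fit_gaussian_ml(
    data: GroupedDataset, opts: MQREOptions | None = None, **kwargs
) -> MQREFit:
    """Classical Gaussian ML random-intercepts fit (squared loss, q = 0.5)."""
    return fit_expectile_re(data, 0.5, opts, **kwargs)
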