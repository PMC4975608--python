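"""Asymptotic inference for q-specific fixed effects.

Standard errors come from a Taylor-linearisation (sandwich) covariance of
the fixed-effects estimating equation: the bread is the observed derivative
of the robust score, the meat the empirical outer product of cluster-level
score contributions (with a d/(d-1) small-sample correction), so within-
group dependence of the scores is fully retained.  Confidence intervals use
the normal approximation.  Variance-component uncertainty is not
propagated (plug-in treatment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import GroupedDataset
from .errors import InvalidParameterError, NotConvergedError
from .estimation import MQREFit, _beta_sandwich

__all__ = ["beta_covariance", "coefficient_table"]


def beta_covariance(fit: MQREFit, data: GroupedDataset) -> np.ndarray:
    """Sandwich covariance matrix of the fixed effects of a converged fit.

    Symmetric positive semidefinite by construction.  Refuses a fit whose
    estimating equations did not converge, since the linearisation is taken
    at a root of the score.
    """
    if not fit.converged:
        raise NotConvergedError(
            "covariance requires a converged fit; inspect fit.eq_norms"
        )
    return _beta_sandwich(data, fit.beta, fit.varcomp, fit.spec)


def coefficient_table(
    fits: list[MQREFit],
    alpha: float = 0.05,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate estimates, SEs and normal CIs across a grid of q values.

    One row per (q, coefficient); columns ``q, term, estimate, se, lower,
    upper``.  All fits must share one design (same number of coefficients).
    """
    if not fits:
        raise InvalidParameterError("empty fit list")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    p = fits[0].beta.shape[0]
    if any(f.beta.shape[0] != p for f in fits):
        raise InvalidParameterError("fits do not share a common design")
    if names is None:
        names = [f"x{k}" for k in range(p)]
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    rows = []
    for f in fits:
        se = np.sqrt(np.diag(f.beta_cov))
        for k in range(p):
            rows.append(
                {
                    "q": f.spec.q,
                    "term": names[k],
                    "estimate": f.beta[k],
                    "se": se[k],
                    "lower": f.beta[k] - z * se[k],
                    "upper": f.beta[k] + z * se[k],
                }
            )
    return pd.DataFrame(rows)
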