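"""Monte-Carlo evaluation study for M-quantile random-effects regression.

Data are generated from the two-level location-shift model

    y_ij = 100 + 2 x_ij + gamma_j + eps_ij,   j = 1..100,

with group sizes n_j in [5, 20] totalling n = 1259 and x ~ U[0, 20], both
held fixed across replicates.  Four error mechanisms probe robustness:

- ``NN``            gamma ~ N(0, 3),   eps ~ N(0, 5)            (model holds)
- ``TT``            gamma ~ t(3),      eps ~ t(3)               (heavy tails)
- ``NLap``          gamma ~ N(0, 3),   eps ~ Laplace(0, 1.58)   (var ~= 5)
- ``contaminated``  gamma ~ N(0, 3) for 90 groups, N(0, 20) for 10;
                    eps ~ 0.9 N(0, 5) + 0.1 N(0, 150)

Each replicate is fitted with the random-effects M-quantile model (MQRE,
Huber c = 1.345), single-level M-quantile regression (MQ, same c) and — at
q = 0.5 — the Gaussian ML random-intercepts model (LRE).  Performance is
summarised by average relative bias (ARB, percent) against the conditional
quantile of the level-1 error, and relative efficiency (EFF), the ratio of
Monte-Carlo variances with MQ as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GroupedDataset
from .errors import InvalidParameterError
from .estimation import MQREOptions, fit_expectile_re, fit_mqre
from .mquantile import MQSpec, fit_mq

__all__ = [
    "SCENARIO_IDS",
    "SimScenario",
    "SimReport",
    "make_scenario",
    "draw_replicate",
    "true_parameters",
    "compute_arb",
    "compute_eff",
    "run_study",
]

SCENARIO_IDS = ("NN", "TT", "NLap", "contaminated")

#: Study design constants.
N_GROUPS = 100
N_TOTAL = 1259
SIZE_LO, SIZE_HI = 5, 20
BETA0, BETA1 = 100.0, 2.0
LAPLACE_SCALE = 1.58  # level-1 variance 2 * 1.58^2 ~= 5
N_CLEAN_GROUPS = 90  # contaminated scenario: groups 91..100 are inflated


@dataclass
class SimScenario:
    """One error-generation mechanism over the shared fixed design."""

    id: str
    group_sizes: np.ndarray
    x1: np.ndarray
    group_idx: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS:
            raise InvalidParameterError(
                f"unknown scenario {self.id!r}; choose from {SCENARIO_IDS}"
            )
        self.group_idx = np.repeat(
            np.arange(self.group_sizes.size), self.group_sizes
        )

    @property
    def n(self) -> int:
        return int(self.group_sizes.sum())

    @property
    def d(self) -> int:
        return self.group_sizes.size

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([np.ones(self.n), self.x1])


def make_scenario(id: str, seed) -> SimScenario:
    """Draw the fixed design (group sizes and covariate) for a scenario.

    Group sizes are i.i.d. uniform on {5..20} then repaired by +-1 moves on
    randomly chosen groups (kept within [5, 20]) until they total exactly
    1259; x1 is drawn once from U[0, 20].  Deterministic given the seed,
    and identical across scenario ids for the same seed, so estimators face
    the same design under every error mechanism.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.integers(SIZE_LO, SIZE_HI + 1, size=N_GROUPS)
    while (diff := N_TOTAL - int(sizes.sum())) != 0:
        j = rng.integers(N_GROUPS)
        if diff > 0 and sizes[j] < SIZE_HI:
            sizes[j] += 1
        elif diff < 0 and sizes[j] > SIZE_LO:
            sizes[j] -= 1
    x1 = rng.uniform(0.0, 20.0, size=N_TOTAL)
    return SimScenario(id=id, group_sizes=sizes, x1=x1)


def draw_replicate(scn: SimScenario, rep_seed) -> GroupedDataset:
    """Draw fresh level-1 and level-2 errors and assemble one replicate."""
    rng = (
        rep_seed
        if isinstance(rep_seed, np.random.Generator)
        else np.random.default_rng(rep_seed)
    )
    d, n = scn.d, scn.n
    if scn.id == "NN":
        gamma = rng.normal(0.0, np.sqrt(3.0), d)
        eps = rng.normal(0.0, np.sqrt(5.0), n)
    elif scn.id == "TT":
        gamma = rng.standard_t(3, d)
        eps = rng.standard_t(3, n)
    elif scn.id == "NLap":
        gamma = rng.normal(0.0, np.sqrt(3.0), d)
        eps = rng.laplace(0.0, LAPLACE_SCALE, n)
    else:  # contaminated
        gamma = np.empty(d)
        gamma[:N_CLEAN_GROUPS] = rng.normal(
            0.0, np.sqrt(3.0), N_CLEAN_GROUPS
        )
        gamma[N_CLEAN_GROUPS:] = rng.normal(
            0.0, np.sqrt(20.0), d - N_CLEAN_GROUPS
        )
        outlier = rng.random(n) < 0.1
        eps = np.where(
            outlier,
            rng.normal(0.0, np.sqrt(150.0), n),
            rng.normal(0.0, np.sqrt(5.0), n),
        )
    y = BETA0 + BETA1 * scn.x1 + gamma[scn.group_idx] + eps
    return GroupedDataset(
        y=y,
        X=scn.X,
        group_idx=scn.group_idx,
        group_labels=np.arange(1, d + 1),
    )


def true_parameters(scn_id: str, q: float) -> tuple[float, float]:
    """Target (intercept, slope) at order q: conditional-quantile convention.

    Under the location-shift model the slope is 2 for every q; the
    intercept is 100 plus the q-quantile of the level-1 error distribution.
    For the contaminated scenario the quantile of the uncontaminated
    N(0, 5) core is used.
    """
    if scn_id in ("NN", "contaminated"):
        shift = stats.norm.ppf(q, scale=np.sqrt(5.0))
    elif scn_id == "TT":
        shift = stats.t.ppf(q, 3)
    elif scn_id == "NLap":
        shift = stats.laplace.ppf(q, scale=LAPLACE_SCALE)
    else:
        raise InvalidParameterError(f"unknown scenario {scn_id!r}")
    return BETA0 + float(shift), BETA1


def compute_arb(estimates, theta: float) -> float:
    """Average relative bias in percent: 100 * mean((est - theta)/theta)."""
    if theta == 0.0:
        raise InvalidParameterError("ARB is undefined for theta = 0")
    est = np.asarray(estimates, dtype=float)
    return float(100.0 * np.mean((est - theta) / theta))


def compute_eff(model_estimates, reference_estimates) -> float:
    """Relative efficiency: ratio of Monte-Carlo variances, model over reference.

    Variances are taken about each sample's own mean with the 1/R
    normalisation; the reference (single-level MQ) against itself gives
    exactly 1.
    """
    m = np.asarray(model_estimates, dtype=float)
    r = np.asarray(reference_estimates, dtype=float)
    if m.size < 2 or r.size < 2:
        raise InvalidParameterError("need at least 2 replicates for EFF")
    v_ref = float(np.var(r))
    if v_ref == 0.0:
        raise InvalidParameterError("reference variance is zero")
    return float(np.var(m)) / v_ref


@dataclass
class SimReport:
    """Aggregated Monte-Carlo results.

    ``table`` holds one row per (scenario, q, estimator, coefficient) with
    the mean estimate, ARB (%), EFF against the MQ reference, empirical and
    mean estimated standard errors, replicate counts and failure counts.
    """

    table: pd.DataFrame
    R: int
    master_seed: int
    c: float

    def lookup(self, scenario, q, estimator, coef):
        """Return the single summary row as a pandas Series."""
        t = self.table
        m = (
            (t.scenario == scenario)
            & (np.isclose(t.q, q))
            & (t.estimator == estimator)
            & (t.coef == coef)
        )
        sub = t[m]
        if len(sub) != 1:
            raise KeyError(
                f"no unique row for ({scenario}, {q}, {estimator}, {coef})"
            )
        return sub.iloc[0]

    def table8(self) -> pd.DataFrame:
        """ARB / EFF / mean-estimate layout per scenario, q and estimator."""
        t = self.table.copy()
        t["cell"] = t.coef.map({0: "b0", 1: "b1"})
        wide = t.pivot_table(
            index=["scenario", "estimator"],
            columns=["q", "cell"],
            values=["arb", "eff", "mean"],
            sort=False,
        )
        return wide

    def table9(self) -> pd.DataFrame:
        """Empirical vs estimated SEs of the MQRE fixed effects."""
        t = self.table[self.table.estimator == "MQRE"].copy()
        t["cell"] = t.coef.map({0: "b0", 1: "b1"})
        return t.pivot_table(
            index=["q", "scenario"],
            columns="cell",
            values=["empirical_se", "estimated_se"],
            sort=False,
        )


def _fit_one(estimator, data, q, c, opts):
    """Fit a single estimator on one replicate; returns (beta, se, ok)."""
    if estimator == "MQ":
        f = fit_mq(data.X, data.y, MQSpec(q=q, c=c))
        return f.beta, None, f.converged
    if estimator == "MQRE":
        f = fit_mqre(
            data,
            MQSpec(q=q, c=c),
            opts,
            predict_effects=False,
        )
    elif estimator == "LRE":
        f = fit_expectile_re(data, q, opts, predict_effects=False)
    else:
        raise InvalidParameterError(f"unknown estimator {estimator!r}")
    se = np.sqrt(np.diag(f.beta_cov))
    return f.beta, se, f.converged


def run_study(
    scenario_ids,
    q_list,
    R: int,
    master_seed: int,
    *,
    c: float = 1.345,
    estimators=("MQRE", "MQ", "LRE"),
    opts: MQREOptions | None = None,
    progress: bool = False,
) -> SimReport:
    """Run the Monte-Carlo study and aggregate ARB/EFF/SE summaries.

    One master seed drives everything: the fixed design uses a dedicated
    substream, and each replicate draws its errors from its own spawned
    substream, so any replicate can be re-run independently.  The LRE
    (Gaussian ML) comparator is fitted at q = 0.5 only.  Replicates whose
    fit fails or does not converge are excluded from that cell's summaries
    and counted in ``n_failed`` — a fit failure never aborts the study.
    """
    if R < 1:
        raise InvalidParameterError("R must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(R + 1)
    design_seed = children[0]
    opts = opts or MQREOptions()

    rows = []
    for scn_id in scenario_ids:
        scn = make_scenario(scn_id, design_seed)
        # {(q, estimator): list of beta draws}; SEs for sandwich-based fits
        betas: dict = {}
        ses: dict = {}
        fails: dict = {}
        for r_i in range(R):
            data = draw_replicate(scn, np.random.default_rng(children[r_i + 1]))
            for q in q_list:
                for est in estimators:
                    if est == "LRE" and not np.isclose(q, 0.5):
                        continue
                    key = (q, est)
                    fails.setdefault(key, 0)
                    try:
                        beta, se, ok = _fit_one(est, data, q, c, opts)
                    except Exception:
                        ok = False
                    if not ok:
                        fails[key] += 1
                        continue
                    betas.setdefault(key, []).append(beta)
                    if se is not None:
                        ses.setdefault(key, []).append(se)
            if progress and (r_i + 1) % 50 == 0:
                print(f"  {scn_id}: replicate {r_i + 1}/{R}")

        for q in q_list:
            ref = np.asarray(betas.get((q, "MQ"), []))
            for est in estimators:
                if est == "LRE" and not np.isclose(q, 0.5):
                    continue
                b = np.asarray(betas.get((q, est), []))
                if b.size == 0:
                    continue
                s = np.asarray(ses.get((q, est), []))
                for k in range(b.shape[1]):
                    theta = true_parameters(scn_id, q)[k]
                    emp_se = (
                        float(np.sqrt(np.var(b[:, k])))
                        if b.shape[0] >= 2
                        else np.nan
                    )
                    if b.shape[0] >= 2 and ref.shape[0] >= 2:
                        eff = compute_eff(b[:, k], ref[:, k])
                    else:
                        eff = np.nan
                    rows.append(
                        {
                            "scenario": scn_id,
                            "q": q,
                            "estimator": est,
                            "coef": k,
                            "mean": float(np.mean(b[:, k])),
                            "arb": compute_arb(b[:, k], theta),
                            "eff": eff,
                            "empirical_se": emp_se,
                            "estimated_se": (
                                float(np.mean(s[:, k])) if s.size else np.nan
                            ),
                            "n_reps": int(b.shape[0]),
                            "n_failed": fails.get((q, est), 0),
                        }
                    )
    return SimReport(
        table=pd.DataFrame(rows), R=R, master_seed=master_seed, c=c
    )
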