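"""Data ingestion, model configuration and result serialization."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GroupedDataset
from .errors import DataError, InvalidParameterError
from .estimation import MQREFit, VarianceComponents
from .mquantile import MQSpec

__all__ = [
    "ModelConfig",
    "read_long_table",
    "fit_to_dict",
    "fit_from_dict",
    "save_fit_json",
    "load_fit_json",
]

logger = logging.getLogger("mqreg")


@dataclass
class ModelConfig:
    """Column mapping and fitting options for a long-format table."""

    response: str
    group: str
    fixed: list[str]
    q_list: list[float] = field(default_factory=lambda: [0.1, 0.25, 0.5, 0.75, 0.9])
    c: float = 1.345
    loss: str = "huber"
    alpha: float = 0.05
    sep: str = ","

    def __post_init__(self) -> None:
        for q in self.q_list:
            if not 0.0 < q < 1.0:
                raise InvalidParameterError(f"q values must be in (0, 1), got {q}")


def read_long_table(path, config: ModelConfig):
    """Read a delimited long-format table into a :class:`GroupedDataset`.

    One row per measurement occasion.  Rows with missing values in any
    referenced column are dropped with a logged count (occasion-level
    missingness is expected in cohort data).  Non-numeric fixed-effect
    columns are expanded to indicator columns with the first-observed level
    as the baseline.  An intercept column is prepended.

    Returns
    -------
    (GroupedDataset, list of str)
        The dataset and the fixed-effect column names (incl. intercept).
    """
    df = pd.read_csv(path, sep=config.sep)
    cols = [config.response, config.group, *config.fixed]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"columns not found in {path}: {missing}")
    n0 = len(df)
    df = df.dropna(subset=cols)
    dropped = n0 - len(df)
    if dropped:
        logger.warning(
            "dropped %d row(s) with missing values in referenced columns", dropped
        )
    if len(df) == 0:
        raise DataError("no complete rows left after dropping missing values")
    y = df[config.response].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise DataError(f"response column {config.response!r} is constant")

    names = ["(Intercept)"]
    columns = [np.ones(len(df))]
    for col in config.fixed:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            names.append(col)
            columns.append(s.to_numpy(dtype=float))
        else:
            levels = pd.unique(s)  # first-appearance order
            for lev in levels[1:]:  # first level is the baseline
                names.append(f"{col}[{lev}]")
                columns.append((s == lev).to_numpy(dtype=float))
    X = np.column_stack(columns)
    data = GroupedDataset.from_arrays(y=y, X=X, groups=df[config.group].to_numpy())
    return data, names


def fit_to_dict(fit: MQREFit, names=None, group_labels=None) -> dict:
    """JSON-serializable summary of a fitted model (exact float round trip)."""
    return {
        "spec": {"q": fit.spec.q, "c": fit.spec.c, "loss": fit.spec.loss},
        "beta": fit.beta.tolist(),
        "coef_names": list(names) if names is not None else None,
        "sigma2_gamma": fit.varcomp.sigma2_gamma,
        "sigma2_eps": fit.varcomp.sigma2_eps,
        "gamma": fit.gamma.tolist(),
        "group_labels": (
            np.asarray(group_labels).tolist() if group_labels is not None else None
        ),
        "beta_cov": fit.beta_cov.tolist(),
        "iterations": fit.iterations,
        "converged": bool(fit.converged),
        "eq_norms": fit.eq_norms.tolist(),
        "boundary_gamma": bool(fit.boundary_gamma),
    }


def fit_from_dict(payload: dict) -> MQREFit:
    """Rebuild an :class:`MQREFit` from :func:`fit_to_dict` output.

    The scaled-residual vector is data-dependent and not serialized; it is
    restored empty.
    """
    return MQREFit(
        spec=MQSpec(**payload["spec"]),
        beta=np.asarray(payload["beta"], dtype=float),
        varcomp=VarianceComponents(
            sigma2_gamma=payload["sigma2_gamma"],
            sigma2_eps=payload["sigma2_eps"],
        ),
        gamma=np.asarray(payload["gamma"], dtype=float),
        scaled_residuals=np.empty(0),
        beta_cov=np.asarray(payload["beta_cov"], dtype=float),
        iterations=payload["iterations"],
        converged=payload["converged"],
        eq_norms=np.asarray(payload["eq_norms"], dtype=float),
        boundary_gamma=payload.get("boundary_gamma", False),
    )


def save_fit_json(fit: MQREFit, path, **kwargs) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit, **kwargs), fh, indent=1)


def load_fit_json(path) -> MQREFit:
    with open(path) as fh:
        return fit_from_dict(json.load(fh))
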