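"""Two-level grouped dataset container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = ["GroupedDataset"]


@dataclass
class GroupedDataset:
    """Long-format two-level data: n observations nested in d groups.

    Attributes
    ----------
    y : ndarray, shape (n,)
        Continuous response.
    X : ndarray, shape (n, p)
        Fixed-effects design (intercept column included explicitly).
    group_idx : ndarray of int, shape (n,)
        Group code of each row, 0..d-1 in first-appearance order.
    group_labels : ndarray, shape (d,)
        Original group labels, aligned with the codes.
    """

    y: np.ndarray
    X: np.ndarray
    group_idx: np.ndarray
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.group_idx = np.asarray(self.group_idx, dtype=np.intp).ravel()
        self.group_labels = np.asarray(self.group_labels)
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.group_idx.shape[0] != n:
            raise DataError("y, X and groups must have the same length")
        d = self.group_labels.shape[0]
        sizes = np.bincount(self.group_idx, minlength=d)
        if sizes.shape[0] != d or np.any(sizes == 0):
            raise DataError("every group must contain at least one row")
        self.group_sizes = sizes

    @classmethod
    def from_arrays(cls, y, X, groups) -> "GroupedDataset":
        """Build a dataset from raw arrays, coding groups in first-appearance order."""
        groups = np.asarray(groups).ravel()
        labels, idx = np.unique(groups, return_inverse=True)
        # np.unique sorts; re-map to first-appearance order
        first_pos = np.array([np.argmax(groups == lab) for lab in labels])
        order = np.argsort(first_pos, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(order.size)
        return cls(
            y=y,
            X=X,
            group_idx=rank[idx],
            group_labels=labels[order],
        )

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def d(self) -> int:
        return self.group_labels.shape[0]

    def group_sum(self, v: np.ndarray) -> np.ndarray:
        """Per-group sums of an n-vector (length-d result)."""
        return np.bincount(self.group_idx, weights=v, minlength=self.d)

    def group_mean(self, v: np.ndarray) -> np.ndarray:
        return self.group_sum(v) / self.group_sizes
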