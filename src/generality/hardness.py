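"""Intrinsic instance-hardness metrics for labelled classification data.

Two measures of how hard an individual instance is to classify, usable as
intrinsic difficulty in a generality analysis of classifier populations:

* ``kdn`` — k-disagreeing neighbours: the fraction of an instance's k
  nearest neighbours (self excluded) carrying a different class label.
  An instance deep inside its own class scores 0, an isolated point
  surrounded by another class scores 1.
* ``tdu`` — unpruned-tree depth: the depth of the leaf that classifies the
  instance in a single unpruned binary decision tree grown on the full
  dataset (root depth 0).  Instances that need many conditions to be told
  apart from other classes get large depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .matrix import ValidationError

__all__ = ["LabelledDataset", "kdn", "tdu"]


@dataclass
class LabelledDataset:
    """Feature table plus class labels; no missing features allowed."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        y = np.asarray(self.labels)
        if x.shape[0] != y.shape[0]:
            raise ValidationError("features and labels disagree in length")
        if x.shape[0] < 1:
            raise ValidationError("empty dataset")
        if np.isnan(x).any():
            raise ValidationError("missing feature values are not supported")
        self.features = x
        self.labels = y

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_col: str | None = None) -> "LabelledDataset":
        """Last column (or ``label_col``) is the class label; the rest are features."""
        if label_col is None:
            label_col = frame.columns[-1]
        y = frame[label_col].to_numpy()
        x = frame.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(x, y)

    @property
    def n(self) -> int:
        return self.features.shape[0]


def _coerce(data, labels) -> LabelledDataset:
    if isinstance(data, LabelledDataset):
        return data
    if labels is None:
        raise ValidationError("labels are required when passing raw features")
    return LabelledDataset(np.asarray(data, dtype=float), np.asarray(labels))


def kdn(data, labels=None, k: int = 10, standardise: bool = True) -> np.ndarray:
    """Per-instance difficulty as the fraction of disagreeing nearest neighbours.

    Distances are Euclidean, by default on z-score standardised features
    (constant features are left unscaled).  Ties at the k-th neighbour are
    broken deterministically towards the lower instance index.
    """
    ds = _coerce(data, labels)
    if k < 1:
        raise ValidationError("k must be at least 1")
    if k >= ds.n:
        raise ValidationError(f"k = {k} must be smaller than the number of instances ({ds.n})")
    x = ds.features
    if standardise:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0.0] = 1.0
        x = (x - mu) / sd
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    # stable sort => among tied distances the lower index comes first
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    disagree = ds.labels[nn] != ds.labels[:, None]
    return disagree.mean(axis=1)


# ----------------------------------------------------------------------
# unpruned decision tree
# ----------------------------------------------------------------------

def _entropy(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _best_split(x: np.ndarray, y: np.ndarray) -> tuple[int, float] | None:
    """Axis-aligned split (feature, threshold) with maximal entropy gain.

    Candidate thresholds are midpoints between consecutive distinct values
    of each feature; ties in gain are broken by (feature index, threshold).
    An unpruned tree grows until its leaves are pure, so when the node is
    impure but no split strictly reduces entropy (e.g. XOR-structured data)
    the first candidate split is taken anyway; every midpoint split leaves
    both children non-empty, so the recursion always terminates.  Returns
    None only when no feature has two distinct values left.
    """
    n = y.shape[0]
    parent = _entropy(y)
    best: tuple[int, float] | None = None
    first: tuple[int, float] | None = None
    best_gain = 1e-12  # prefer strict entropy reductions
    for f in range(x.shape[1]):
        vals = np.unique(x[:, f])
        if vals.size < 2:
            continue
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (lo + hi)
            if first is None:
                first = (f, thr)
            left = x[:, f] <= thr
            nl = int(left.sum())
            child = (nl * _entropy(y[left]) + (n - nl) * _entropy(y[~left])) / n
            gain = parent - child
            if gain > best_gain + 1e-15:
                best_gain, best = gain, (f, thr)
            # equal gain keeps the earlier (feature, threshold) pair
    return best if best is not None else first


class _Node:
    __slots__ = ("split", "left", "right", "depth")

    def __init__(self, depth: int):
        self.split: tuple[int, float] | None = None
        self.left: "_Node | None" = None
        self.right: "_Node | None" = None
        self.depth = depth


def _grow(x: np.ndarray, y: np.ndarray, depth: int, depths_out: np.ndarray, idx: np.ndarray) -> None:
    node_split = None
    if np.unique(y).size > 1:
        node_split = _best_split(x, y)
    if node_split is None:
        depths_out[idx] = depth
        return
    f, thr = node_split
    mask = x[:, f] <= thr
    _grow(x[mask], y[mask], depth + 1, depths_out, idx[mask])
    _grow(x[~mask], y[~mask], depth + 1, depths_out, idx[~mask])


def tdu(data, labels=None) -> np.ndarray:
    """Per-instance difficulty as leaf depth in one unpruned decision tree.

    The tree uses binary entropy-gain splits at midpoints between sorted
    distinct feature values and grows until every leaf is pure or
    unsplittable (identical feature rows with mixed labels stop early;
    zero-gain splits are still taken while distinct values remain, so
    XOR-structured data is separated rather than abandoned at the root).
    The root has depth 0, so a single-class dataset scores 0 everywhere.
    """
    ds = _coerce(data, labels)
    if ds.n < 1:
        raise ValidationError("empty dataset")
    depths = np.zeros(ds.n, dtype=int)
    _grow(ds.features, ds.labels, 0, depths, np.arange(ds.n))
    return depths
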