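"""Minimum-redundancy maximum-relevance (mRMR) feature selection.

Features are discretized into equal-width bins and mutual information (MI)
is estimated by the empirical plug-in on the joint histogram, in bits.
Greedy forward selection then maximizes, at each step, either

* ``difference`` (MID):  I(i, c) - (1/|sel|) * sum_{j in sel} I(i, j)
* ``quotient``   (MIQ):  I(i, c) / max((1/|sel|) * sum_{j in sel} I(i, j), eps)

where I(i, c) is the relevance of feature *i* to the class labels and the
mean pairwise MI against the already-selected set is the redundancy. Ties
break by lexicographic feature name, so rankings are deterministic across
runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

#: Redundancy floor for the quotient criterion's zero-redundancy first steps.
QUOTIENT_EPS = 1e-12


@dataclass
class DiscretizedMatrix:
    """Integer bin codes per feature plus the binning metadata."""

    codes: np.ndarray  # (n_samples, n_features) int64, dense per column
    n_levels: np.ndarray  # occupied levels per feature
    bin_edges: List[np.ndarray]
    feature_names: List[str]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.codes.shape


def _dense_codes(x: np.ndarray) -> np.ndarray:
    """Relabel integer codes to consecutive 0..m-1 preserving order."""
    _, inv = np.unique(x, return_inverse=True)
    return inv.astype(np.int64)


def discretize(
    table: Union[pd.DataFrame, np.ndarray], bin_count: int = 10
) -> DiscretizedMatrix:
    """Equal-width binning of each feature over its observed range.

    Constant features map to a single code; occupied bins are relabelled to
    consecutive codes (so a 0/1 feature keeps codes 0/1 for any bin count).
    """
    if bin_count < 2:
        raise ValueError("bin_count must be >= 2")
    if isinstance(table, pd.DataFrame):
        names = [str(c) for c in table.columns]
        X = table.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(table, dtype=np.float64)
        names = [f"x{i}" for i in range(X.shape[1])]
    bad = ~np.isfinite(X)
    if bad.any():
        j = int(np.flatnonzero(bad.any(axis=0))[0])
        raise ValueError(f"non-finite values in feature {names[j]!r}")
    n, d = X.shape
    codes = np.zeros((n, d), dtype=np.int64)
    levels = np.ones(d, dtype=np.int64)
    edges: List[np.ndarray] = []
    mins, maxs = X.min(axis=0), X.max(axis=0)
    for j in range(d):
        lo, hi = mins[j], maxs[j]
        if hi > lo:
            e = np.linspace(lo, hi, bin_count + 1)
            raw = np.minimum(
                ((X[:, j] - lo) / (hi - lo) * bin_count).astype(np.int64),
                bin_count - 1,
            )
            codes[:, j] = _dense_codes(raw)
            levels[j] = codes[:, j].max() + 1
            edges.append(e)
        else:
            edges.append(np.array([lo, hi]))
    return DiscretizedMatrix(codes, levels, edges, names)


def _mi_from_joint(counts: np.ndarray) -> float:
    """Plug-in MI (bits) from a 2-D joint-count histogram."""
    n = counts.sum()
    p = counts / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pi * pj))
    return float(max(np.nansum(terms), 0.0))


def mutual_information(x: Sequence[int], y: Sequence[int]) -> float:
    """Empirical mutual information between two discrete vectors, in bits.

    Symmetric (exactly: the argument pair is canonically ordered before the
    histogram is built), non-negative, and zero-count cells contribute 0.
    """
    x = _dense_codes(np.asarray(x))
    y = _dense_codes(np.asarray(y))
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("empty input")
    if x.tobytes() > y.tobytes():  # canonical order for exact symmetry
        x, y = y, x
    nx, ny = x.max() + 1, y.max() + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_joint(joint)


def _mi_columns_vs(codes: np.ndarray, levels: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI (bits) of every column of ``codes`` against discrete vector ``y``.

    Vectorized: one global bincount over per-column-offset combined codes.
    """
    n, d = codes.shape
    m = int(levels.max())
    b = int(y.max()) + 1
    combined = codes * b + y[:, None]
    offsets = (np.arange(d, dtype=np.int64) * (m * b))[None, :]
    flat = (combined + offsets).ravel()
    counts = np.bincount(flat, minlength=d * m * b).reshape(d, m, b)
    p = counts / n
    pi = p.sum(axis=2, keepdims=True)
    pj = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pi * pj))
    mi = np.nansum(terms, axis=(1, 2))
    return np.maximum(mi, 0.0)


def relevance(
    disc: DiscretizedMatrix, labels: Sequence[int]
) -> pd.Series:
    """Per-feature relevance I(i, c) against the class labels, in bits."""
    y = _dense_codes(np.asarray(labels))
    if y.max() == 0:
        warnings.warn("single-class labels: all relevances are 0")
        return pd.Series(np.zeros(disc.shape[1]), index=disc.feature_names)
    mi = _mi_columns_vs(disc.codes, disc.n_levels, y)
    return pd.Series(mi, index=disc.feature_names)


def relevance_of_set(disc: DiscretizedMatrix, labels: Sequence[int]) -> float:
    """Set-level relevance: the mean of the per-feature I(i, c) values."""
    return float(relevance(disc, labels).mean())


@dataclass
class MrmrResult:
    """Ordered mRMR ranking with per-step relevance/redundancy accounting."""

    ranked_features: List[str]
    per_step: pd.DataFrame  # columns: feature, relevance, redundancy, score
    variant: str

    def to_tsv(self, path: str) -> None:
        self.per_step.to_csv(path, sep="\t", index=False)

    def to_namelist(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.ranked_features) + "\n")


def mrmr_select(
    table: Union[pd.DataFrame, np.ndarray],
    labels: Sequence[int],
    k: int,
    variant: str = "difference",
    bin_count: int = 10,
) -> MrmrResult:
    """Greedy forward mRMR selection of ``k`` features.

    Step 1 picks the feature with maximal relevance I(i, c); later steps
    maximize the MID or MIQ criterion, with redundancy measured only against
    the already-selected features (incremental mRMR). Deterministic: ties
    break by feature name.
    """
    if variant not in ("difference", "quotient"):
        raise ValueError(f"unknown variant {variant!r}")
    disc = discretize(table, bin_count)
    n, d = disc.shape
    if not 1 <= k <= d:
        raise ValueError(f"k={k} outside [1, {d}]")
    if np.all(disc.n_levels == 1):
        raise ValueError("all features are constant")
    y = _dense_codes(np.asarray(labels))
    if y.size != n:
        raise ValueError("labels length does not match table rows")
    rel = relevance(disc, y).to_numpy()
    names = np.asarray(disc.feature_names, dtype=object)

    selected: List[int] = []
    red_sum = np.zeros(d)
    candidate = np.ones(d, dtype=bool)
    records = []
    for _ in range(k):
        if selected:
            red = red_sum / len(selected)
            if variant == "difference":
                crit = rel - red
            else:
                crit = rel / np.maximum(red, QUOTIENT_EPS)
        else:
            red = np.zeros(d)
            crit = rel.copy()
        masked = np.where(candidate, crit, -np.inf)
        best_val = masked.max()
        ties = np.flatnonzero(masked == best_val)
        pick = ties[np.argmin(names[ties])] if ties.size > 1 else ties[0]
        records.append(
            {
                "feature": names[pick],
                "relevance": rel[pick],
                "redundancy": red[pick],
                "score": crit[pick],
            }
        )
        selected.append(int(pick))
        candidate[pick] = False
        red_sum += _mi_columns_vs(
            disc.codes, disc.n_levels, disc.codes[:, pick]
        )
    return MrmrResult(
        ranked_features=[str(names[i]) for i in selected],
        per_step=pd.DataFrame(records),
        variant=variant,
    )


def top_k_slice(result: MrmrResult, k: int) -> List[str]:
    """Prefix of the ranked feature list; nested across k by construction."""
    if k > len(result.ranked_features):
        raise ValueError(
            f"k={k} exceeds ranking length {len(result.ranked_features)}"
        )
    return result.ranked_features[:k]


class MRMRSelector(SelectorMixin, BaseEstimator):
    """sklearn feature selector implementing greedy mRMR.

    Parameters
    ----------
    k : int
        Number of features to select.
    variant : {"difference", "quotient"}
        MID (numerically safer, the default) or MIQ criterion.
    bin_count : int
        Equal-width bins for the plug-in MI estimator.

    Attributes
    ----------
    ranking_ : list of str
        Selected feature names in pick order.
    result_ : MrmrResult
        Full per-step relevance/redundancy/score record.
    """

    def __init__(self, k: int = 10, variant: str = "difference", bin_count: int = 10):
        self.k = k
        self.variant = variant
        self.bin_count = bin_count

    def fit(self, X, y) -> "MRMRSelector":
        X_arr, y_arr = validate_data(self, X, y, dtype=np.float64)
        names = getattr(
            self,
            "feature_names_in_",
            np.asarray([f"x{i}" for i in range(X_arr.shape[1])], dtype=object),
        )
        frame = pd.DataFrame(X_arr, columns=list(names))
        self.result_ = mrmr_select(
            frame, y_arr, k=self.k, variant=self.variant, bin_count=self.bin_count
        )
        self.ranking_ = list(self.result_.ranked_features)
        name_to_idx = {n: i for i, n in enumerate(names)}
        mask = np.zeros(X_arr.shape[1], dtype=bool)
        mask[[name_to_idx[n] for n in self.ranking_]] = True
        self.support_ = mask
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
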