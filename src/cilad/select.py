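"""Hybrid feature selection: ReliefF weights fused with Pearson correlation.

The combined score is ``alpha * RF + (1 - alpha) * |PC|`` after both signals
are min-max rescaled to [0, 1]; features are ranked by the combined score
with ties broken by original column order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import FeatureTable


class ConstantFeatureWarning(UserWarning):
    """A feature (or the target) is constant; its correlation is defined as 0."""


def _minmax_columns(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (X - lo) / rng


def relieff_weights(X: FeatureTable, k_neighbors: int = 10,
                    n_iterations: int | None = None, seed: int = 0,
                    literal_sign: bool = False) -> np.ndarray:
    """ReliefF feature weights.

    Features are min-max scaled internally; neighbors are found by L1
    distance.  For each visited instance the weight of feature ``f`` changes
    by ``delta * (NMAD_f - NHD_f)`` where ``NHD`` is the mean per-feature
    distance to the k nearest same-class hits, ``NMAD`` the class-prior
    weighted mean over the k nearest misses of every other class, and
    ``delta = 1 / n_iterations`` so weights are averages.  ``literal_sign``
    flips the update to ``NHD - NMAD`` (rewarding far hits), matching a
    printed variant of the rule rather than the classical orientation.

    ``n_iterations=None`` visits all instances in deterministic order;
    otherwise a seeded subsample without replacement is visited.
    """
    y = np.asarray(X.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF requires at least 2 classes")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= counts.min():
        raise ValueError(
            f"k_neighbors={k_neighbors} must be smaller than the smallest "
            f"class size ({counts.min()})")
    Xs = _minmax_columns(X.values)
    n, d = Xs.shape
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    if n_iterations is None:
        visit = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        visit = rng.choice(n, size=min(n_iterations, n), replace=False)
    delta = 1.0 / len(visit)
    class_idx = {c: np.flatnonzero(y == c) for c in classes}
    w = np.zeros(d)
    for i in visit:
        diffs = np.abs(Xs - Xs[i])          # (n, d) per-feature distances
        dist = diffs.sum(axis=1)            # total L1 distance
        c_i = y[i]
        # nearest hits (exclude self); stable order for deterministic ties
        hits = class_idx[c_i]
        hits = hits[hits != i]
        order = hits[np.argsort(dist[hits], kind="stable")][:k_neighbors]
        nhd = diffs[order].mean(axis=0)
        nmad = np.zeros(d)
        denom = 1.0 - priors[c_i]
        for c in classes:
            if c == c_i:
                continue
            miss = class_idx[c]
            order = miss[np.argsort(dist[miss], kind="stable")][:k_neighbors]
            nmad += (priors[c] / denom) * diffs[order].mean(axis=0)
        if literal_sign:
            w += delta * (nhd - nmad)
        else:
            w += delta * (nmad - nhd)
    return w


def pearson_scores(X: FeatureTable) -> np.ndarray:
    """Pearson correlation of each feature with the integer-coded target.

    A constant feature (or target) yields a correlation of 0 with a warning.
    """
    y = np.asarray(X.labels, dtype=float)
    sy = y.std()
    out = np.zeros(X.n_features)
    if sy == 0:
        warnings.warn("constant target; all correlations set to 0",
                      ConstantFeatureWarning)
        return out
    yc = y - y.mean()
    for j in range(X.n_features):
        col = X.values[:, j]
        sx = col.std()
        if sx == 0:
            warnings.warn(f"constant feature {X.names[j]!r}; correlation set to 0",
                          ConstantFeatureWarning)
            continue
        out[j] = float(np.mean((col - col.mean()) * yc) / (sx * sy))
    return out


@dataclass
class SelectionScores:
    """Per-feature selection signals and the fused ranking."""

    names: list[str]
    relieff: np.ndarray
    pearson: np.ndarray
    relieff_scaled: np.ndarray
    pearson_scaled: np.ndarray
    combined: np.ndarray
    rank: np.ndarray  # 1-based rank of each feature by combined, descending
    alpha: float

    def ordered(self) -> np.ndarray:
        """Feature indices from best (rank 1) to worst."""
        return np.argsort(self.rank, kind="stable")


def _rescale01(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def combine_scores(relieff, pearson, alpha: float = 0.5,
                   names: list[str] | None = None) -> SelectionScores:
    """Fuse ReliefF and Pearson signals: ``alpha * RF + (1 - alpha) * |PC|``.

    Both inputs are min-max rescaled to [0, 1] (the absolute value of the
    Pearson correlation is taken first).  Ranks are assigned by descending
    combined score; ties break by ascending feature index.
    """
    rf = np.asarray(relieff, dtype=float)
    pc = np.asarray(pearson, dtype=float)
    if rf.shape != pc.shape:
        raise ValueError("relieff and pearson must have equal lengths")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rf_s = _rescale01(rf)
    pc_s = _rescale01(np.abs(pc))
    combined = alpha * rf_s + (1.0 - alpha) * pc_s
    n = len(combined)
    order = np.lexsort((np.arange(n), -combined))  # descending, index tiebreak
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    if names is None:
        names = [f"feature_{j}" for j in range(n)]
    return SelectionScores(list(names), rf, pc, rf_s, pc_s, combined, rank, alpha)


def select_top(scores: SelectionScores, k: int | None = None,
               threshold: float | None = None) -> np.ndarray:
    """Indices of the top-k features by rank, or of all features whose
    combined score meets ``threshold``.  Exactly one criterion is required."""
    if (k is None) == (threshold is None):
        raise ValueError("provide exactly one of k or threshold")
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        return scores.ordered()[:k]
    sel = np.flatnonzero(scores.combined >= threshold)
    if sel.size == 0:
        warnings.warn("threshold exceeds the maximum combined score; "
                      "empty selection", UserWarning)
    return sel[np.argsort(scores.rank[sel], kind="stable")]


def score_features(X: FeatureTable, alpha: float = 0.5, k_neighbors: int = 10,
                   n_iterations: int | None = None, seed: int = 0) -> SelectionScores:
    """Convenience: ReliefF + Pearson + fusion in one call."""
    rf = relieff_weights(X, k_neighbors=k_neighbors, n_iterations=n_iterations,
                         seed=seed)
    pc = pearson_scores(X)
    return combine_scores(rf, pc, alpha=alpha, names=X.names)
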