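"""K-modes clustering of categorical sequences (sklearn-style estimator).

K-modes is the K-means analogue for categorical data: the dissimilarity
is the Hamming (simple matching) distance, and the cluster centre is the
per-position mode of its members. This implementation is fully
deterministic given ``random_state``:

* modes initialise as k distinct observed patterns sampled without
  replacement (warning + duplicates when fewer distinct patterns exist);
* assignment ties go to the lowest cluster index;
* a mode-update tie retains the previous mode's symbol when that symbol
  is among the tied ones, else takes the first tied symbol in category
  order;
* an empty cluster is reseeded with the pattern farthest from its
  currently assigned mode (skipped when every distance is already 0);
* of ``n_init`` restarts the lowest-cost one wins, earliest restart on
  ties.

The total cost is guaranteed non-increasing across iterations within a
restart; this is asserted at every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin


@dataclass(frozen=True)
class CategoricalPattern:
    """An ordered categorical sequence for one compound."""

    compound_id: str
    symbols: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.symbols)


def hamming_dissimilarity(a, b) -> int:
    """Number of positions at which two equal-length sequences differ."""
    sa = a.symbols if isinstance(a, CategoricalPattern) else tuple(a)
    sb = b.symbols if isinstance(b, CategoricalPattern) else tuple(b)
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return int(sum(x != y for x, y in zip(sa, sb)))


def _encode(X: Sequence, categories: Sequence[str] | None):
    """Rows of symbols -> int code matrix; category order fixes tie-breaks.

    Without explicit *categories* the order of first appearance in the
    data is used, which makes results invariant under bijective renaming
    of the symbols.
    """
    rows = [
        tuple(x.symbols) if isinstance(x, CategoricalPattern) else tuple(x) for x in X
    ]
    if not rows:
        raise ValueError("no patterns to cluster")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("all patterns must have equal length")
    if categories is None:
        cats: list = []
        for r in rows:
            for s in r:
                if s not in cats:
                    cats.append(s)
    else:
        cats = list(categories)
        unknown = {s for r in rows for s in r} - set(cats)
        if unknown:
            raise ValueError(f"symbols outside declared categories: {sorted(unknown)}")
    code = {s: i for i, s in enumerate(cats)}
    M = np.array([[code[s] for s in r] for r in rows], dtype=np.int64)
    return M, cats


class KModes(ClusterMixin, BaseEstimator):
    """K-modes clusterer for equal-length categorical sequences.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k.
    n_init : int
        Independent random restarts; the lowest-cost run is kept.
    max_iter : int
        Iteration cap per restart.
    random_state : int or None
        Seed for initial-mode sampling.
    categories : sequence of str or None
        Symbol order used for mode-update tie-breaking. Defaults to the
        order of first appearance in the data.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster index per input pattern.
    cluster_modes_ : list of tuple
        Final mode sequence per cluster (decoded symbols).
    cost_ : int
        Total Hamming distance of patterns to their assigned modes.
    n_iter_ : int
        Iterations of the winning restart.
    """

    def __init__(self, n_clusters=3, n_init=50, max_iter=100, random_state=None,
                 categories=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state
        self.categories = categories

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _distances(X: np.ndarray, modes: np.ndarray) -> np.ndarray:
        # (n, k) Hamming distances
        return (X[:, None, :] != modes[None, :, :]).sum(axis=2)

    def _update_modes(self, X, labels, modes, n_cats):
        k, L = modes.shape
        new = modes.copy()
        for j in range(k):
            members = X[labels == j]
            if len(members) == 0:
                continue
            for pos in range(L):
                counts = np.bincount(members[:, pos], minlength=n_cats)
                top = counts.max()
                tied = np.flatnonzero(counts == top)
                prev = modes[j, pos]
                new[j, pos] = prev if prev in tied else tied[0]
        return new

    def _single_run(self, X, n_cats, rng):
        n, L = X.shape
        k = self.n_clusters
        uniq = np.unique(X, axis=0)
        if len(uniq) >= k:
            idx = rng.choice(len(uniq), size=k, replace=False)
            modes = uniq[idx].copy()
        else:
            warnings.warn(
                f"only {len(uniq)} distinct patterns for k={k}; "
                "duplicated initial modes", stacklevel=2,
            )
            extra = rng.choice(n, size=k - len(uniq), replace=True)
            modes = np.vstack([uniq, X[extra]]).copy()

        prev_labels = None
        prev_cost = None
        n_iter = 0
        labels = np.zeros(n, dtype=int)
        for n_iter in range(1, self.max_iter + 1):
            D = self._distances(X, modes)
            labels = D.argmin(axis=1)  # argmin takes lowest index on ties
            point_d = D[np.arange(n), labels]
            # reseed empty clusters with the farthest point from its mode
            for j in range(k):
                if (labels == j).any():
                    continue
                far = int(point_d.argmax())
                if point_d[far] == 0:
                    continue  # nothing to gain; leave the cluster empty
                labels[far] = j
                modes[j] = X[far]
                point_d[far] = 0
            cost = int(point_d.sum())
            if prev_cost is not None and cost > prev_cost:
                raise RuntimeError(
                    f"k-modes cost increased ({prev_cost} -> {cost}); "
                    "tie-break rules violated"
                )
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                break
            prev_labels = labels.copy()
            prev_cost = cost
            modes = self._update_modes(X, labels, modes, n_cats)
        return labels, modes, cost, n_iter

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Cluster the patterns in X (rows of symbols or CategoricalPattern)."""
        if self.n_clusters <= 0:
            raise ValueError(f"n_clusters must be positive, got {self.n_clusters}")
        M, cats = self._encode_input(X)
        n = len(M)
        if self.n_clusters > n:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds n={n} patterns")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            labels, modes, cost, n_iter = self._single_run(M, len(cats), rng)
            if best is None or cost < best[2]:
                best = (labels, modes, cost, n_iter)
        labels, modes, cost, n_iter = best
        self.categories_ = tuple(cats)
        self.labels_ = labels
        self._modes_code = modes
        self.cluster_modes_ = [tuple(cats[c] for c in row) for row in modes]
        self.cost_ = cost
        self.n_iter_ = n_iter
        self.n_features_in_ = M.shape[1]
        return self

    def _encode_input(self, X):
        return _encode(X, self.categories)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        """Assign new patterns to the nearest fitted mode."""
        if not hasattr(self, "labels_"):
            raise RuntimeError("KModes instance is not fitted yet")
        M, _ = _encode(X, self.categories_)
        if M.shape[1] != self.n_features_in_:
            raise ValueError("pattern length differs from fitted data")
        return self._distances(M, self._modes_code).argmin(axis=1)


@dataclass
class KModesResult:
    """Plain record of one K-modes fit on named patterns."""

    labels: dict[str, int]
    modes: list[tuple[str, ...]]
    cost: int
    n_iter: int
    seed: int | None


def kmodes_fit(
    patterns: Sequence[CategoricalPattern],
    k: int,
    seed: int | None = None,
    n_init: int = 50,
    max_iter: int = 100,
    categories: Sequence[str] | None = None,
) -> KModesResult:
    """Functional wrapper over :class:`KModes` keyed by compound id."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(patterns):
        raise ValueError(f"k={k} exceeds number of patterns ({len(patterns)})")
    distinct = {p.symbols for p in patterns}
    if len(distinct) < k:
        warnings.warn(
            f"only {len(distinct)} distinct patterns for k={k}", stacklevel=2
        )
    est = KModes(n_clusters=k, n_init=n_init, max_iter=max_iter,
                 random_state=seed, categories=categories)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-mode warning already issued
        est.fit(patterns)
    return KModesResult(
        labels={p.compound_id: int(l) for p, l in zip(patterns, est.labels_)},
        modes=est.cluster_modes_,
        cost=est.cost_,
        n_iter=est.n_iter_,
        seed=seed,
    )
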