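"""Validation layer: property-space clustering, overlap, rank tests.

Do compounds that are removed alike also *look* alike chemically? The
module clusters compounds in (z-scored) descriptor space with K-means,
counts the overlap between property-based and removal-based clusterings
under the optimal injective cluster correspondence, and tests each
descriptor's distribution across removal clusters with the
Kruskal–Wallis H test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2, rankdata
from sklearn.cluster import KMeans

from .core import ClusterAssignment, DescriptorTable, DESCRIPTOR_COLUMNS


def zscore_columns(matrix: np.ndarray) -> np.ndarray:
    """Centre and scale each column to mean 0, sd 1 (population sd).

    Constant columns cannot be scaled; they become all-zero with a
    warning so distance-based clustering simply ignores them.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) set to zero", stacklevel=2
        )
        sd = np.where(constant, 1.0, sd)
    return (M - mean) / sd


def kmeans_descriptors(
    features: pd.DataFrame | DescriptorTable,
    k: int,
    seed: int | None = 0,
    n_init: int = 10,
) -> ClusterAssignment:
    """K-means on z-scored descriptors; k mirrors the paired removal clustering."""
    if isinstance(features, DescriptorTable):
        features = features.data
    ids = list(features.index)
    X = features.to_numpy(dtype=float)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of compounds ({len(ids)})")
    Z = zscore_columns(X) if len(ids) >= 2 else X
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    return ClusterAssignment(
        method="property", labels={c: int(l) for c, l in zip(ids, labels)}
    )


@dataclass
class OverlapResult:
    """Agreement between a removal clustering and a property clustering."""

    contingency: pd.DataFrame  # rows: removal clusters, cols: property clusters
    mapping: dict  # removal label -> property label (injective)
    matched_count: int
    n: int

    @property
    def matched_percent(self) -> float:
        return 100.0 * self.matched_count / self.n

    def to_dict(self) -> dict:
        return {
            "contingency": {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.contingency.iterrows()
            },
            "mapping": {str(k): str(v) for k, v in self.mapping.items()},
            "matched_count": self.matched_count,
            "matched_percent": round(self.matched_percent, 6),
            "n": self.n,
        }


def overlap_count(
    removal: ClusterAssignment, property_: ClusterAssignment
) -> OverlapResult:
    """Count compounds in corresponding cells of two clusterings.

    The correspondence is the injective row-to-column assignment of the
    contingency matrix maximising the total matched count (the smaller
    side is injected into the larger), found by optimal assignment.
    """
    a, b = set(removal.labels), set(property_.labels)
    if a != b:
        diff = sorted(a.symmetric_difference(b))
        raise ValueError(f"compound sets differ; symmetric difference: {diff}")
    compounds = sorted(a)
    r = pd.Series([removal.labels[c] for c in compounds], name="removal")
    p = pd.Series([property_.labels[c] for c in compounds], name="property")
    contingency = pd.crosstab(r, p)
    C = contingency.to_numpy()
    # maximise the matched sum over injective row->col assignments
    rows, cols = linear_sum_assignment(C, maximize=True)
    mapping = {
        contingency.index[i]: contingency.columns[j] for i, j in zip(rows, cols)
    }
    matched = int(C[rows, cols].sum())
    return OverlapResult(
        contingency=contingency, mapping=mapping, matched_count=matched,
        n=len(compounds),
    )


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; chi-square p-value.

    ``H = 12 / (n (n+1)) * sum_i R_i^2 / n_i - 3 (n+1)`` on mid-ranks,
    divided by the tie-correction factor ``1 - sum(t^3 - t)/(n^3 - n)``.
    With every value identical the statistic degenerates to (0, 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must be parallel")
    labels, inverse = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = rankdata(values)  # mid-ranks for ties
    H = 0.0
    for g in range(len(labels)):
        r = ranks[inverse == g]
        if len(r) == 0:
            raise ValueError(f"group {labels[g]!r} is empty")
        H += r.sum() ** 2 / len(r)
    H = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))
    if tie == 0.0:  # all values identical
        return 0.0, 1.0
    H /= tie
    p = float(chi2.sf(H, df=len(labels) - 1))
    return float(H), p


def descriptor_tests_by_cluster(
    descriptors: DescriptorTable,
    assignment: ClusterAssignment,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One Kruskal–Wallis test per descriptor across removal clusters.

    Returns a 7-row table (feature, H, p, significant at *alpha*, and a
    Bonferroni-adjusted column for transparency; the headline flag uses
    the unadjusted p).
    """
    common = sorted(set(descriptors.compounds) & set(assignment.labels))
    if not common:
        raise ValueError("no compound is present in both inputs")
    labels = np.array([assignment.labels[c] for c in common])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if (counts == 1).any():
        warnings.warn(
            "cluster(s) with a single compound: low-power comparison",
            stacklevel=2,
        )
    rows = []
    m = len(DESCRIPTOR_COLUMNS)
    for feature in DESCRIPTOR_COLUMNS:
        vals = descriptors.data.loc[common, feature].to_numpy()
        H, p = kruskal_wallis(vals, labels)
        rows.append(
            {
                "feature": feature,
                "H": H,
                "p": p,
                "significant": bool(p < alpha),
                "p_bonferroni": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)
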