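"""Unsupervised discrimination assessment: hierarchical clustering on
Euclidean distances, cluster purity against known class labels,
silhouette widths, and consensus clustering over resampled runs with the
consensus-index empirical CDF.

The consensus index of a sample pair is the number of resampled runs
assigning both samples to the same cluster divided by the number of runs
in which both were selected; pairs never co-selected are undefined (NaN)
and excluded from the CDF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, ValidationError
from .matrix import ExpressionMatrix

LINKAGES = ("complete", "average", "ward")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise sample distances, zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.isfinite(v).all():
            raise DataError("distance matrix contains NaN or infinite values")
        if not np.allclose(v, v.T, atol=1e-9):
            raise DataError("distance matrix is not symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) over samples."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray = field(repr=False)
    method: str = "complete"

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


@dataclass
class ConsensusMatrix:
    """Co-clustering and co-selection counts from resampled clustering."""

    sample_ids: list[str]
    cocluster: np.ndarray = field(repr=False)
    coselect: np.ndarray = field(repr=False)

    @property
    def index(self) -> np.ndarray:
        """Consensus index: co-cluster / co-selection; NaN where undefined, 1 on diagonal."""
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = np.where(self.coselect > 0, self.cocluster / np.maximum(self.coselect, 1), np.nan)
        np.fill_diagonal(idx, 1.0)
        return idx


@dataclass
class SilhouetteResult:
    widths: pd.Series = field(repr=False)  # per sample, in [-1, 1]
    cluster_means: pd.Series = field(repr=False)
    overall_mean: float = 0.0


def euclidean_distances(m: ExpressionMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample feature vectors."""
    if m.n_samples < 2:
        raise ValidationError("need at least 2 samples for distances")
    X = m.data.to_numpy(dtype=float).T
    if not np.isfinite(X).all():
        raise DataError("expression matrix contains NaN values")
    return DistanceMatrix(m.sample_ids, squareform(pdist(X, metric="euclidean")))


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a distance matrix."""
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    if d.n < 2:
        raise ValidationError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(d.condensed(), method=linkage)
    return Dendrogram(d.sample_ids, Z, linkage)


def cut_to_k(t: Dendrogram, k: int) -> pd.Series:
    """Cut the tree into k clusters; labels 1..k by order of first member.

    If merge-height ties make exactly k unattainable the nearest
    attainable number is returned with a warning.
    """
    if not (1 <= k <= t.n):
        raise ValidationError(f"k must lie in [1, {t.n}]")
    flat = hierarchy.fcluster(t.linkage_matrix, t=k, criterion="maxclust")
    got = len(np.unique(flat))
    if got != k:
        warnings.warn(f"requested k={k} unattainable; returning {got} clusters", stacklevel=2)
    relabel: dict[int, int] = {}
    out = np.empty(len(flat), dtype=int)
    for i, c in enumerate(flat):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[i] = relabel[c]
    return pd.Series(out, index=pd.Index(t.sample_ids, name="sample_id"), name="cluster")


def cluster_purity(assignment: pd.Series, labels: pd.Series) -> float:
    """Fraction of samples in their cluster's majority class.

    purity = (sum over clusters of the majority-class count) / n.  A tie
    for the majority contributes ceil(cluster_size / 2).
    """
    if len(assignment) == 0:
        raise ValidationError("empty cluster assignment")
    labels = labels.reindex(assignment.index)
    if labels.isna().any():
        raise DataError("class labels missing for some assigned samples")
    total = 0
    for _, members in assignment.groupby(assignment):
        counts = labels.loc[members.index].value_counts()
        top = int(counts.iloc[0])
        if (counts == top).sum() > 1:
            top = math.ceil(len(members) / 2)
        total += top
    return total / len(assignment)


def silhouette(d: DistanceMatrix, assignment: pd.Series) -> SilhouetteResult:
    """Silhouette widths s(i) = (b - a) / max(a, b); singletons get 0."""
    a = assignment.reindex(d.sample_ids)
    if a.isna().any():
        raise DataError("assignment missing samples present in the distance matrix")
    clusters = a.unique()
    if len(clusters) < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    D = d.values
    labels = a.to_numpy()
    widths = np.zeros(d.n)
    for i in range(d.n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0
            continue
        a_i = D[i, own].sum() / (n_own - 1)
        b_i = min(
            D[i, labels == c].mean() for c in clusters if c != labels[i]
        )
        denom = max(a_i, b_i)
        widths[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    widths_s = pd.Series(widths, index=pd.Index(d.sample_ids, name="sample_id"))
    cluster_means = widths_s.groupby(a.to_numpy()).mean()
    return SilhouetteResult(widths_s, cluster_means, float(widths_s.mean()))


def consensus_cluster(
    m: ExpressionMatrix,
    k: int,
    n_resamples: int = 200,
    sample_frac: float = 0.8,
    linkage: str = "complete",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ConsensusMatrix:
    """Consensus clustering by sample resampling without replacement.

    Each run subsamples floor(sample_frac * n) samples, clusters them
    (Euclidean distance + the chosen linkage) and cuts to k; co-cluster
    and co-selection counts accumulate across runs.
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    if not (0 < sample_frac <= 1):
        raise ValidationError("sample_frac must lie in (0, 1]")
    if k < 2:
        raise ValidationError("k must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    full = euclidean_distances(m)
    n = full.n
    m_sub = max(int(math.floor(sample_frac * n)), 2)
    cocluster = np.zeros((n, n))
    coselect = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m_sub, replace=False))
        sub = DistanceMatrix([full.sample_ids[i] for i in idx], full.values[np.ix_(idx, idx)])
        flat = hierarchy.fcluster(
            hierarchy.linkage(sub.condensed(), method=linkage), t=k, criterion="maxclust"
        )
        sel = np.zeros(n, dtype=bool)
        sel[idx] = True
        coselect[np.ix_(idx, idx)] += 1
        for c in np.unique(flat):
            members = idx[flat == c]
            cocluster[np.ix_(members, members)] += 1
    return ConsensusMatrix(list(m.sample_ids), cocluster, coselect)


def consensus_cdf(c: ConsensusMatrix) -> pd.DataFrame:
    """Empirical CDF of defined upper-triangle consensus-index values.

    Returns a frame with columns ``index_value`` (sorted unique values)
    and ``cumulative_fraction`` (fraction of defined pairs <= value).
    """
    idx = c.index
    iu = np.triu_indices(len(c.sample_ids), k=1)
    vals = idx[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise DataError("no defined off-diagonal consensus pairs")
    xs = np.unique(vals)
    cdf = np.searchsorted(np.sort(vals), xs, side="right") / vals.size
    return pd.DataFrame({"index_value": xs, "cumulative_fraction": cdf})
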