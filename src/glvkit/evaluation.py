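"""Scoring predicted against observed trajectories.

Dynamic Time Warping (DTW) compares two series of equal or unequal
length by finding the monotone warping path with the smallest summed
absolute difference.  The dynamic-programming recursion is

    DTW(i, j) = |T1(i) - T2(j)| + min(DTW(i-1, j),
                                      DTW(i-1, j-1),
                                      DTW(i, j-1))

with DTW(1, 1) = |T1(1) - T2(1)| and the final distance in the
(m, n) cell — i.e. the plain unconstrained recursion, no warping
window and no step weighting.

Each series is min-max scaled to [0, 1] before the comparison so that
shape, not magnitude, drives the score.  Per-taxon distances are
summed into a single cumulative score, and all-vs-all DTW distance
matrices over the taxa (within the observed set and within the
predicted set) feed hierarchically clustered dendrograms whose
agreement reflects how well the predicted community structure matches
the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory
from .errors import ValidationError
from .tables import AbundanceTable

__all__ = [
    "DTWReport",
    "DistanceMatrix",
    "Dendrogram",
    "DendrogramNode",
    "dtw_distance",
    "scale01",
    "compare_trajectories",
    "all_vs_all_dtw",
    "hierarchical_cluster",
]


def dtw_distance(t1, t2) -> float:
    """Dynamic Time Warping distance with absolute-difference cost.

    Both series must be non-empty and finite; lengths may differ.
    """
    a = np.asarray(t1, dtype=float).ravel()
    b = np.asarray(t2, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("DTW requires non-empty series")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("DTW requires finite series")
    m, n = a.size, b.size
    # cost[i, j] = |a_i - b_j|; cumulative matrix filled row by row
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.empty_like(cost)
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    acc[1:, 0] = cost[1:, 0].cumsum() + cost[0, 0]
    for i in range(1, m):
        row_prev = acc[i - 1]
        row = acc[i]
        for j in range(1, n):
            row[j] = cost[i, j] + min(row_prev[j], row_prev[j - 1], row[j - 1])
    return float(acc[m - 1, n - 1])


def scale01(series) -> np.ndarray:
    """Min-max scale a series to [0, 1]; constant series map to zeros."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("cannot scale an empty series")
    if not np.all(np.isfinite(x)):
        raise ValidationError("cannot scale a non-finite series")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValidationError("distances must be >= 0")


@dataclass
class DendrogramNode:
    """One node of a rooted binary merge tree (leaf iff label set)."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    """Agglomerative merge tree; heights non-decreasing root-ward."""

    root: DendrogramNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        """Canonical newick string: children sorted by smallest leaf,
        branch lengths = parent merge height minus child height."""

        def render(node: DendrogramNode) -> str:
            if node.is_leaf:
                return node.label.replace(" ", "_")
            kids = sorted(node.children, key=lambda c: min(c.leaves()))
            parts = [
                f"{render(c)}:{node.height - c.height:.12g}" for c in kids
            ]
            return "(" + ",".join(parts) + ")"

        return render(self.root) + ";"


def hierarchical_cluster(
    dm: DistanceMatrix, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    ``linkage`` is one of ``average`` (UPGMA, default), ``single`` or
    ``complete``.  Ties are broken deterministically by merging the
    pair whose (lexicographically smallest) representative labels sort
    first.
    """
    if linkage not in {"average", "single", "complete"}:
        raise ValidationError(f"unknown linkage {linkage!r}")
    k = len(dm.labels)
    if k < 2:
        raise ValidationError("clustering needs at least 2 labels")

    # active clusters: representative label -> (node, member indices)
    clusters: dict[str, tuple[DendrogramNode, list[int]]] = {
        lab: (DendrogramNode(height=0.0, label=lab), [i])
        for i, lab in enumerate(dm.labels)
    }
    D = dm.values

    def cluster_dist(ia: list[int], ib: list[int]) -> float:
        block = D[np.ix_(ia, ib)]
        if linkage == "average":
            return float(block.mean())
        if linkage == "single":
            return float(block.min())
        return float(block.max())

    while len(clusters) > 1:
        best = None
        for ra in sorted(clusters):
            for rb in sorted(clusters):
                if rb <= ra:
                    continue
                d = cluster_dist(clusters[ra][1], clusters[rb][1])
                key = (d, ra, rb)
                if best is None or key < best:
                    best = key
        d, ra, rb = best
        node_a, idx_a = clusters.pop(ra)
        node_b, idx_b = clusters.pop(rb)
        height = max(d, node_a.height, node_b.height)  # enforce monotone
        merged = DendrogramNode(height=height, children=(node_a, node_b))
        clusters[min(ra, rb)] = (merged, idx_a + idx_b)
    (root, _) = next(iter(clusters.values()))
    return Dendrogram(root=root)


def all_vs_all_dtw(
    series_by_taxon: dict[str, np.ndarray], scaled: bool = True
) -> DistanceMatrix:
    """DTW distance between every pair of taxa's (scaled) series."""
    labels = list(series_by_taxon)
    prepared = {
        t: scale01(s) if scaled else np.asarray(s, dtype=float)
        for t, s in series_by_taxon.items()
    }
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = dtw_distance(prepared[labels[i]], prepared[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


@dataclass
class DTWReport:
    """Per-taxon and cumulative DTW scores plus community dendrograms."""

    per_taxon_distance: dict[str, float]
    cumulative: float
    observed_matrix: DistanceMatrix
    predicted_matrix: DistanceMatrix
    observed_tree: Dendrogram | None
    predicted_tree: Dendrogram | None


def compare_trajectories(
    observed: AbundanceTable,
    predicted: Trajectory | AbundanceTable,
    scaled: bool = True,
    linkage: str = "average",
) -> DTWReport:
    """Score a predicted trajectory set against observations.

    Taxa must coincide as sets (order-insensitive); series lengths may
    differ.  Per-taxon distances use min-max scaled series (unless
    ``scaled=False``); the cumulative score is their unweighted sum.
    """
    obs_taxa, pred_taxa = set(observed.taxa), set(predicted.taxa)
    if obs_taxa != pred_taxa:
        raise ValidationError(
            "observed and predicted taxa differ; symmetric difference: "
            f"{sorted(obs_taxa ^ pred_taxa)}"
        )
    taxa = list(observed.taxa)
    obs_series = {t: observed.series(t) for t in taxa}
    pred_series = {t: predicted.series(t) for t in taxa}

    per_taxon: dict[str, float] = {}
    for t in taxa:
        a = scale01(obs_series[t]) if scaled else obs_series[t]
        b = scale01(pred_series[t]) if scaled else pred_series[t]
        per_taxon[t] = dtw_distance(a, b)
    cumulative = float(sum(per_taxon.values()))

    obs_dm = all_vs_all_dtw(obs_series, scaled=scaled)
    pred_dm = all_vs_all_dtw(pred_series, scaled=scaled)
    obs_tree = hierarchical_cluster(obs_dm, linkage) if len(taxa) >= 2 else None
    pred_tree = hierarchical_cluster(pred_dm, linkage) if len(taxa) >= 2 else None
    return DTWReport(
        per_taxon_distance=per_taxon,
        cumulative=cumulative,
        observed_matrix=obs_dm,
        predicted_matrix=pred_dm,
        observed_tree=obs_tree,
        predicted_tree=pred_tree,
    )
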