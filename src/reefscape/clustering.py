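"""Unsupervised density-based clustering of the averaged distance matrix.

HDBSCAN is run directly on the precomputed averaged distance matrix; it
requires no preset number of clusters and leaves samples it judges too
isolated unassigned (label -1). Two final selection strategies are exposed:
"eom" (excess of mass, coarser) and "leaf" (tree leaves, finer). Cluster ids
are remapped to descending cluster size for stable reporting. The resulting
partition is compared with predefined labels through a row-percentage
contingency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .features import CategoryLabel

__all__ = [
    "ClusterAssignment",
    "ContingencyMatrix",
    "cluster",
    "contingency",
    "cluster_purity",
]


@dataclass
class ClusterAssignment:
    """Per-sample integer cluster ids; -1 marks unassigned samples."""

    labels: np.ndarray
    method: str  # "eom" or "leaf"
    min_cluster_size: int
    min_samples: int | None = None

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels)) - (1 if -1 in self.labels else 0))

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.labels) - {-1})


@dataclass
class ContingencyMatrix:
    """Composition of each cluster in terms of a label's categories (row %)."""

    cluster_ids: list[int]  # -1 first if present, then ascending
    categories: list[str]
    values: np.ndarray  # row percentages, each row sums to 100

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cluster_ids, columns=self.categories)

    def to_csv(self, path: Path | str) -> None:
        self.to_dataframe().to_csv(path, index_label="cluster")


def _remap_by_size(raw: np.ndarray) -> np.ndarray:
    """Renumber cluster ids to 0..k-1 by descending cluster size (-1 kept)."""
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping.get(x, -1) for x in raw], dtype=int)


def cluster(
    avg_distance: np.ndarray,
    min_cluster_size: int = 100,
    method: str = "eom",
    min_samples: int | None = None,
) -> ClusterAssignment:
    """HDBSCAN over a precomputed (averaged) distance matrix.

    ``min_samples`` defaults to the implementation's default (equal to
    ``min_cluster_size``). When fewer than ``min_cluster_size`` samples
    exist, no cluster can form and every sample is returned as -1.
    """
    D = np.asarray(avg_distance, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {D.shape}")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if D.min() < 0:
        raise ValueError("distance matrix must be nonnegative")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if method not in ("eom", "leaf"):
        raise ValueError(f"method must be 'eom' or 'leaf', got {method!r}")

    n = D.shape[0]
    if n < min_cluster_size or (min_samples is not None and n < min_samples):
        labels = np.full(n, -1, dtype=int)
    else:
        model = HDBSCAN(
            min_cluster_size=min_cluster_size,
            min_samples=min_samples,
            cluster_selection_method=method,
            metric="precomputed",
            copy=True,
        ).fit(D)
        labels = _remap_by_size(np.asarray(model.labels_, dtype=int))
    return ClusterAssignment(
        labels=labels,
        method=method,
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
    )


def contingency(assignment: ClusterAssignment, labels: CategoryLabel) -> ContingencyMatrix:
    """Row-percentage composition of each cluster over the label's categories.

    Rows are ordered -1 first (if any sample is unassigned), then ascending
    cluster ids; every row sums to 100.
    """
    if len(assignment.labels) != len(labels.values):
        raise ValueError("assignment and labels cover different sample counts")
    ids = ([-1] if -1 in assignment.labels else []) + assignment.cluster_ids
    cats = labels.categories
    values = np.zeros((len(ids), len(cats)))
    for r, cid in enumerate(ids):
        mask = assignment.labels == cid
        total = mask.sum()
        for c, cat in enumerate(cats):
            values[r, c] = 100.0 * np.sum(mask & (labels.values == cat)) / total
    return ContingencyMatrix(ids, list(cats), values)


def cluster_purity(
    assignment: ClusterAssignment,
    labels: CategoryLabel,
    include_noise: bool = False,
) -> float:
    """Best-mapping purity of the clustering against a reference label.

    Each cluster is mapped to its majority category; purity is the fraction
    of samples whose category matches their cluster's majority, computed
    over assigned samples only unless ``include_noise`` (then -1 counts as
    one more cluster).
    """
    mask = np.ones(len(assignment.labels), dtype=bool)
    if not include_noise:
        mask = assignment.labels >= 0
        if not mask.any():
            raise ValueError("no assigned samples; purity undefined")
    correct = 0
    for cid in set(assignment.labels[mask]):
        in_cluster = mask & (assignment.labels == cid)
        _, counts = np.unique(labels.values[in_cluster], return_counts=True)
        correct += counts.max()
    return float(correct / mask.sum())
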