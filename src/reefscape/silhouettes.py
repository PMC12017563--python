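"""Pairwise silhouette separation between categories of a label.

For two categories A and B of a categorical label, the distance matrix is
restricted to the samples of A and B and each sample i gets the classic
silhouette value s(i) = (b - a) / max(a, b), where a is its mean distance to
its own category (self excluded) and b its mean distance to the other
category. The pairwise index is the mean of s over the samples of *both*
categories. A value near 1 means the two categories occupy disjoint regions
of the acoustic space; near 0, that they overlap completely. Values can be
slightly negative when clouds interpenetrate; they are reported unclamped
even though the index is usually discussed on the 0-1 range.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .features import CategoryLabel

__all__ = ["SilhouetteMatrix", "pairwise_silhouette", "silhouette_matrix"]


@dataclass
class SilhouetteMatrix:
    """Symmetric matrix of pairwise silhouette indices (diagonal undefined)."""

    label_name: str
    categories: list[str]
    values: np.ndarray  # (n_categories, n_categories), NaN diagonal

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.categories, columns=self.categories)

    def to_csv(self, path: Path | str) -> None:
        self.to_dataframe().to_csv(path, index_label=self.label_name)

    def pair(self, cat_a: str, cat_b: str) -> float:
        ia, ib = self.categories.index(cat_a), self.categories.index(cat_b)
        return float(self.values[ia, ib])

    @property
    def n_pairs(self) -> int:
        n = len(self.categories)
        return n * (n - 1) // 2


def pairwise_silhouette(
    avg_distance: np.ndarray,
    labels: CategoryLabel,
    cat_a: str,
    cat_b: str,
) -> float:
    """Mean silhouette of the samples of two categories against each other.

    Duplicate points (a == b == 0) contribute s(i) = 0. Symmetric in its
    category arguments by construction.
    """
    if cat_a == cat_b:
        raise ValueError(f"categories must differ, got {cat_a!r} twice")
    D = np.asarray(avg_distance, dtype=np.float64)
    idx_a, idx_b = labels.indices(cat_a), labels.indices(cat_b)
    for cat, idx in ((cat_a, idx_a), (cat_b, idx_b)):
        if len(idx) < 2:
            raise ValueError(
                f"category {cat!r} has {len(idx)} sample(s); need at least 2"
            )
    s_values = []
    for own, other in ((idx_a, idx_b), (idx_b, idx_a)):
        n_own = len(own)
        within = D[np.ix_(own, own)]
        a = (within.sum(axis=1) - np.diag(within)) / (n_own - 1)
        b = D[np.ix_(own, other)].mean(axis=1)
        denom = np.maximum(a, b)
        s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
        s_values.append(s)
    return float(np.concatenate(s_values).mean())


def silhouette_matrix(avg_distance: np.ndarray, labels: CategoryLabel) -> SilhouetteMatrix:
    """Fill all unordered category pairs of a label into a symmetric matrix."""
    cats = labels.categories
    if len(cats) < 2:
        raise ValueError(f"label {labels.name!r} has fewer than 2 categories")
    n = len(cats)
    values = np.full((n, n), np.nan)
    for (i, ca), (j, cb) in combinations(enumerate(cats), 2):
        values[i, j] = values[j, i] = pairwise_silhouette(avg_distance, labels, ca, cb)
    return SilhouetteMatrix(labels.name, list(cats), values)
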