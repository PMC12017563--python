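"""Temporal trajectories of soundscapes in the projection space.

Ordering a group's samples by window start time traces a path through the
acoustic space. Because absolute UMAP coordinates are meaningless, the
trajectory metric is *relative*: within each UMAP repeat, a group's
reference point is the centroid of the first point of each of its
replicates' paths (the "average starting point", shared across replicates),
and distances from that reference are divided by the mean distance between
the reference and its k nearest sample points (k = 100 by default, reduced
and recorded when fewer points exist). Across the N repeats the per-time
median and the first/ninth deciles are retained. A stationary soundscape
hovers around 1; excursions (a rain squall, a passing boat fleet, dusk)
push the median up and back.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import ProjectionEnsemble
from .features import SampleRecord

__all__ = ["TrajectorySeries", "path_points", "relative_trajectory"]


@dataclass
class TrajectorySeries:
    """Ensemble-stabilized relative distances of one (group, replicate) path."""

    group: str
    replicate: str
    times: list[datetime]
    median_rel_distance: np.ndarray
    interdecile_low: np.ndarray  # decile 1
    interdecile_high: np.ndarray  # decile 9
    k_neighbors: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "median": self.median_rel_distance,
                "decile1": self.interdecile_low,
                "decile9": self.interdecile_high,
            }
        )

    def to_csv(self, path: Path | str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _select(samples: list[SampleRecord], selector: dict[str, str]) -> np.ndarray:
    return np.array(
        [
            i
            for i, s in enumerate(samples)
            if all(s.labels.get(k) == v for k, v in selector.items())
        ],
        dtype=int,
    )


def path_points(
    embedding: np.ndarray,
    samples: list[SampleRecord],
    selector: dict[str, str],
) -> tuple[list[datetime], np.ndarray]:
    """Time-ordered points of one path (e.g. one site-replicate).

    Returns the ordered window-start times and the corresponding points of
    ``embedding`` (one per aggregated sample). Raises if the selector
    matches nothing.
    """
    idx = _select(samples, selector)
    if len(idx) == 0:
        raise ValueError(f"no samples match {selector}")
    order = np.argsort([samples[i].window_start for i in idx], kind="stable")
    idx = idx[order]
    return [samples[i].window_start for i in idx], np.asarray(embedding)[idx]


def relative_trajectory(
    ensemble: ProjectionEnsemble,
    samples: list[SampleRecord],
    group_label: str,
    group: str,
    replicate_label: str = "replicate",
    k: int = 100,
) -> dict[str, TrajectorySeries]:
    """Relative-distance trajectories of one group, per replicate.

    Within each repeat of the ensemble: the reference is the centroid of the
    first-time point of each replicate's path (pooled across replicates);
    the scale is the mean distance from the reference to its k nearest
    sample points (all samples eligible); each path point's value is its
    distance to the reference divided by that scale. The per-time median and
    deciles 1/9 over repeats are returned for each replicate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    group_idx = _select(samples, {group_label: group})
    if len(group_idx) == 0:
        raise ValueError(f"no samples with {group_label} == {group!r}")
    replicates = sorted({samples[i].labels[replicate_label] for i in group_idx})

    paths: dict[str, np.ndarray] = {}
    times: dict[str, list[datetime]] = {}
    first_points: list[int] = []
    for rep in replicates:
        idx = _select(samples, {group_label: group, replicate_label: rep})
        order = np.argsort([samples[i].window_start for i in idx], kind="stable")
        idx = idx[order]
        paths[rep] = idx
        times[rep] = [samples[i].window_start for i in idx]
        first_points.append(idx[0])

    n_total = ensemble.n_samples
    k_eff = min(k, n_total)
    rel: dict[str, list[np.ndarray]] = {rep: [] for rep in replicates}
    for r in range(ensemble.n_repeats):
        points = ensemble.embeddings[r]
        ref = points[first_points].mean(axis=0)
        dist_all = np.linalg.norm(points - ref, axis=1)
        scale = np.sort(dist_all)[:k_eff].mean()
        if scale <= 0:
            raise ValueError("degenerate scale: all nearest points coincide with the reference")
        for rep in replicates:
            rel[rep].append(dist_all[paths[rep]] / scale)

    out: dict[str, TrajectorySeries] = {}
    for rep in replicates:
        stack = np.vstack(rel[rep])  # (n_repeats, n_times)
        out[rep] = TrajectorySeries(
            group=group,
            replicate=rep,
            times=times[rep],
            median_rel_distance=np.median(stack, axis=0),
            interdecile_low=np.quantile(stack, 0.1, axis=0, method="linear"),
            interdecile_high=np.quantile(stack, 0.9, axis=0, method="linear"),
            k_neighbors=k_eff,
        )
    return out
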