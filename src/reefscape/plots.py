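"""Static plot helpers (matrices as heat grids, trajectory bands, point maps).

Convenience surface over matplotlib; not part of the computational results.
"""

from __future__ import annotations

import numpy as np

from .silhouettes import SilhouetteMatrix
from .trajectories import TrajectorySeries

__all__ = ["plot_matrix", "plot_trajectory", "plot_embedding"]


def plot_matrix(matrix: SilhouetteMatrix | object, ax=None, cmap: str = "viridis"):
    """Heat-grid of a silhouette or contingency matrix with category ticks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = matrix.to_dataframe()
    im = ax.imshow(df.to_numpy(), cmap=cmap)
    ax.set_xticks(range(len(df.columns)), [str(c) for c in df.columns], rotation=90)
    ax.set_yticks(range(len(df.index)), [str(i) for i in df.index])
    ax.figure.colorbar(im, ax=ax)
    return ax


def plot_trajectory(series: TrajectorySeries, ax=None, color=None):
    """Median relative distance over time with the interdecile band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = series.times
    ax.plot(t, series.median_rel_distance, color=color,
            label=f"{series.group} / {series.replicate}")
    ax.fill_between(t, series.interdecile_low, series.interdecile_high,
                    alpha=0.25, color=color)
    ax.set_xlabel("time")
    ax.set_ylabel("relative distance to starting point")
    ax.legend()
    return ax


def plot_embedding(points: np.ndarray, labels=None, ax=None):
    """2-D scatter of an embedding (first two components), colored by label."""
    import matplotlib.pyplot as plt

    points = np.asarray(points)
    if ax is None:
        _, ax = plt.subplots()
    if labels is None:
        ax.scatter(points[:, 0], points[:, 1], s=8)
    else:
        labels = np.asarray(labels, dtype=object)
        for cat in dict.fromkeys(labels):
            mask = labels == cat
            ax.scatter(points[mask, 0], points[mask, 1], s=8, label=str(cat))
        ax.legend(markerscale=2)
    return ax
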