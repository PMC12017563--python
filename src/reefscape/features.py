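"""From per-second embeddings to the analysis-ready feature matrix.

Consecutive per-second embedding vectors of each recording are averaged over
the *integration time* (a positive integer number of seconds, 15 s by
default, i.e. 4 samples per one-minute file) into one sample each; trailing
partial blocks are discarded. Dimensions that are constant over the whole
dataset carry no information and are pruned, and the remaining dimensions
are robust-scaled: ``x -> (x - median) / IQR`` with linearly interpolated
(type-7) quartiles. The default pipeline order is aggregate -> prune ->
scale; the alternative order (prune and scale the per-second vectors, then
aggregate) is available via the ``order`` switch of the pipeline since both
readings of the workflow are defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .campaign import RecordingEntry
from .embeddings import EmbeddingVector

__all__ = [
    "PRUNE_TOL",
    "SampleRecord",
    "FeatureMatrix",
    "CategoryLabel",
    "aggregate",
    "prune_dims",
    "robust_scale",
    "composite_label",
    "label_from_samples",
]

#: max - min at or below which a dimension is considered constant
PRUNE_TOL = 1e-12

#: IQR at or below which the scaler falls back to (max - min)
IQR_TOL = 1e-12

#: separator used to join constituent categories into a composite label
COMPOSITE_SEP = "/"


@dataclass
class SampleRecord:
    """One aggregated acoustic sample (an integration-time window)."""

    entry: RecordingEntry | None
    window_start: datetime
    integration_time: float
    labels: dict[str, str] = field(default_factory=dict)


@dataclass
class FeatureMatrix:
    """n_samples x n_dims features with per-row sample provenance."""

    values: np.ndarray
    samples: list[SampleRecord]
    dim_names: list[str]
    #: per-dimension (median, scale, fallback) recorded by robust_scale
    scaling_params: pd.DataFrame | None = None
    #: names of dimensions removed by prune_dims
    pruned_dims: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-d")
        if self.values.shape[0] != len(self.samples):
            raise ValueError("rows and samples misaligned")
        if self.values.shape[1] != len(self.dim_names):
            raise ValueError("columns and dim_names misaligned")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def sample_table(self) -> pd.DataFrame:
        """Samples as a DataFrame (window start, source file, labels)."""
        rows = []
        for s in self.samples:
            row = {
                "window_start": s.window_start,
                "integration_time": s.integration_time,
                "file": str(s.entry.file_path) if s.entry else "",
            }
            row.update(s.labels)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CategoryLabel:
    """A named categorical labelling of samples with an ordered category list."""

    name: str
    values: np.ndarray  # per-sample category strings
    categories: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=object)
        missing = set(self.values) - set(self.categories)
        if missing:
            raise ValueError(f"values outside declared categories: {sorted(missing)}")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def indices(self, category: str) -> np.ndarray:
        if category not in self.categories:
            raise KeyError(f"{category!r} is not a category of label {self.name!r}")
        return np.flatnonzero(self.values == category)


def aggregate(
    per_second_vectors: list[EmbeddingVector],
    integration_time: float,
    entry: RecordingEntry | None = None,
) -> list[tuple[SampleRecord, np.ndarray]]:
    """Average consecutive per-second vectors into integration-time samples.

    Vectors must be in time order and belong to one recording. Blocks are
    non-overlapping; a trailing block shorter than ``integration_time`` is
    discarded. ``integration_time`` must be a positive integer number of
    seconds.
    """
    if integration_time <= 0 or abs(integration_time - round(integration_time)) > 1e-9:
        raise ValueError(
            f"integration_time must be a positive integer number of seconds, "
            f"got {integration_time}"
        )
    it = int(round(integration_time))
    if not per_second_vectors:
        return []
    entry = entry or (per_second_vectors[0].segment.source if per_second_vectors[0].segment else None)
    stack = np.vstack([v.values for v in per_second_vectors])
    n_blocks = len(per_second_vectors) // it
    out: list[tuple[SampleRecord, np.ndarray]] = []
    start0 = entry.start_time if entry is not None else datetime(2000, 1, 1)
    offset0 = per_second_vectors[0].segment.offset if per_second_vectors[0].segment else 0.0
    labels = dict(entry.labels) if entry is not None else {}
    for b in range(n_blocks):
        rec = SampleRecord(
            entry=entry,
            window_start=start0 + timedelta(seconds=offset0 + b * it),
            integration_time=float(it),
            labels=dict(labels),
        )
        out.append((rec, stack[b * it : (b + 1) * it].mean(axis=0)))
    return out


def prune_dims(matrix: FeatureMatrix, tol: float = PRUNE_TOL) -> FeatureMatrix:
    """Drop dimensions that are constant (max - min <= tol) over all samples."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to identify constant dimensions")
    span = matrix.values.max(axis=0) - matrix.values.min(axis=0)
    keep = span > tol
    if not keep.any():
        raise ValueError("no informative dimensions: every column is constant")
    removed = [n for n, k in zip(matrix.dim_names, keep) if not k]
    return FeatureMatrix(
        values=matrix.values[:, keep],
        samples=matrix.samples,
        dim_names=[n for n, k in zip(matrix.dim_names, keep) if k],
        scaling_params=matrix.scaling_params,
        pruned_dims=matrix.pruned_dims + removed,
    )


def robust_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Center on the median and scale by the IQR, per dimension.

    Quartiles use linear interpolation (type 7). A non-constant column whose
    IQR is degenerate (<= 1e-12) is scaled by its range instead; the
    fallback is flagged per column in ``scaling_params``.
    """
    v = matrix.values
    median = np.median(v, axis=0)
    q1, q3 = np.quantile(v, [0.25, 0.75], axis=0, method="linear")
    iqr = q3 - q1
    span = v.max(axis=0) - v.min(axis=0)
    fallback = iqr <= IQR_TOL
    scale = np.where(fallback, span, iqr)
    if np.any(scale <= 0):
        raise ValueError("constant column encountered; prune before scaling")
    params = pd.DataFrame(
        {"median": median, "scale": scale, "range_fallback": fallback},
        index=matrix.dim_names,
    )
    return FeatureMatrix(
        values=(v - median) / scale,
        samples=matrix.samples,
        dim_names=list(matrix.dim_names),
        scaling_params=params,
        pruned_dims=list(matrix.pruned_dims),
    )


def composite_label(labels: dict[str, str], names: list[str]) -> str:
    """Join constituent categories with '/' in the declared order."""
    return COMPOSITE_SEP.join(labels[n] for n in names)


def label_from_samples(
    samples: list[SampleRecord],
    name: str | list[str],
) -> CategoryLabel:
    """Build a CategoryLabel from sample metadata.

    ``name`` may be a single label name or a list of names, in which case a
    composite label (categories joined with '/') is built. Categories are
    ordered by first appearance.
    """
    if isinstance(name, str):
        values = [s.labels[name] for s in samples]
        label_name = name
    else:
        values = [composite_label(s.labels, name) for s in samples]
        label_name = COMPOSITE_SEP.join(name)
    categories = list(dict.fromkeys(values))
    return CategoryLabel(label_name, np.array(values, dtype=object), categories)
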