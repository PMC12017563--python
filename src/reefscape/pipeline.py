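"""End-to-end orchestration: campaign -> features -> ensemble -> analyses.

``run`` executes the full batch workflow and returns (and optionally saves)
a self-describing results bundle: the feature matrix, the projection
ensemble and its averaged distance matrix, per-label silhouette matrices,
HDBSCAN assignments with label contingencies, per-site relative
trajectories, and stability diagnostics. Defaults follow a typical reef
campaign analysis: mel-spectrum embedding over 70-2000 Hz, 15 s integration,
100 3-D UMAP repeats, HDBSCAN minimum cluster size 100, trajectory
normalization over 100 nearest neighbours.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .campaign import FilterSpec, read_campaign, segment_recording
from .clustering import ClusterAssignment, ContingencyMatrix, cluster, contingency
from .embeddings import EmbeddingAdapter, MelSpec, embedder
from .ensemble import (
    ConvergenceSeries,
    ProjectionEnsemble,
    TopologyScores,
    convergence,
    run_ensemble,
    topology_scores,
)
from .features import (
    FeatureMatrix,
    CategoryLabel,
    SampleRecord,
    aggregate,
    label_from_samples,
    prune_dims,
    robust_scale,
)
from .silhouettes import SilhouetteMatrix, silhouette_matrix
from .trajectories import TrajectorySeries, relative_trajectory

__all__ = ["RunConfig", "ResultsBundle", "run", "build_features"]

logger = logging.getLogger("reefscape")

BUNDLE_VERSION = "1"


@dataclass(frozen=True)
class RunConfig:
    """Every knob of the batch pipeline, with campaign-analysis defaults."""

    # embedding
    embedding: str = "mel_spectrum"  # mel_spectrum | mel_spectrogram | cnn_adapter
    fmin: float = 70.0
    fmax: float = 2000.0
    n_mels: int = 64
    n_fft: int = 2048
    hop_s: float = 0.01
    # preprocessing
    highpass_hz: float = 70.0
    highpass_order: int = 8
    segment_length_s: float = 1.0
    # feature table
    integration_time_s: int = 15
    pipeline_order: str = "aggregate_first"  # or "scale_first"
    # projection ensemble
    projection: str = "umap"  # umap | pca
    n_components: int = 3
    n_repeats: int = 100
    n_neighbors: int = 15
    min_dist: float = 0.1
    base_seed: int = 0
    # clustering
    min_cluster_size: int = 100
    min_samples: int | None = None
    cluster_methods: tuple[str, ...] = ("eom", "leaf")
    # trajectories
    trajectory_k: int = 100
    group_label: str = "site"
    replicate_label: str = "replicate"
    # diagnostics
    diagnostics_k: int = 100
    diagnostics_triplets: int = 50_000

    def mel_spec(self) -> MelSpec:
        return MelSpec(
            n_mels=self.n_mels, fmin=self.fmin, fmax=self.fmax,
            n_fft=self.n_fft, hop_s=self.hop_s,
        )

    def filter_spec(self) -> FilterSpec | None:
        if self.highpass_hz <= 0:
            return None
        return FilterSpec(cutoff_hz=self.highpass_hz, order=self.highpass_order)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=str, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        raw["cluster_methods"] = tuple(raw["cluster_methods"])
        return cls(**raw)


@dataclass
class ResultsBundle:
    """All outputs of one pipeline run; reloadable without the audio."""

    config: RunConfig
    features: FeatureMatrix
    ensemble: ProjectionEnsemble
    labels: dict[str, CategoryLabel]
    silhouettes: dict[str, SilhouetteMatrix]
    clusters: dict[str, ClusterAssignment]
    contingencies: dict[str, dict[str, ContingencyMatrix]]
    trajectories: dict[str, dict[str, TrajectorySeries]]
    convergence: ConvergenceSeries | None
    topology: TopologyScores | None
    version: str = BUNDLE_VERSION

    def save(self, path: Path | str) -> Path:
        from .bundle import save_bundle

        return save_bundle(self, path)


def build_features(
    entries,
    config: RunConfig,
    adapter: EmbeddingAdapter | None = None,
) -> FeatureMatrix:
    """Embed, aggregate, prune and scale a campaign into a FeatureMatrix.

    With the default ``pipeline_order="aggregate_first"`` the per-second
    embeddings are averaged over the integration time before pruning and
    robust scaling; ``"scale_first"`` prunes and scales the per-second
    matrix and aggregates afterwards. The two orders give different (both
    defensible) matrices; the switch exists so the sensitivity can be
    checked on any dataset.
    """
    if config.pipeline_order not in ("aggregate_first", "scale_first"):
        raise ValueError(f"unknown pipeline_order {config.pipeline_order!r}")
    embed = embedder(config.embedding, config.mel_spec(), adapter, fallback_to_mel=True)
    fspec = config.filter_spec()

    per_entry_vectors = []
    for entry in entries:
        segs = segment_recording(entry, fspec, config.segment_length_s)
        per_entry_vectors.append(([embed(s) for s in segs], entry))

    if config.pipeline_order == "aggregate_first":
        samples: list[SampleRecord] = []
        rows: list[np.ndarray] = []
        for vectors, entry in per_entry_vectors:
            for rec, vec in aggregate(vectors, config.integration_time_s, entry):
                samples.append(rec)
                rows.append(vec)
        dim_names = per_entry_vectors[0][0][0].dim_names
        matrix = FeatureMatrix(np.vstack(rows), samples, list(dim_names))
        return robust_scale(prune_dims(matrix))

    # scale_first: prune/scale the per-second matrix, then aggregate blocks
    sec_samples: list[SampleRecord] = []
    sec_rows: list[np.ndarray] = []
    spans: list[tuple[int, int, object]] = []
    for vectors, entry in per_entry_vectors:
        start = len(sec_rows)
        for rec, vec in aggregate(vectors, 1, entry):
            sec_samples.append(rec)
            sec_rows.append(vec)
        spans.append((start, len(sec_rows), entry))
    dim_names = per_entry_vectors[0][0][0].dim_names
    per_second = robust_scale(
        prune_dims(FeatureMatrix(np.vstack(sec_rows), sec_samples, list(dim_names)))
    )
    it = int(config.integration_time_s)
    samples, rows = [], []
    for start, stop, entry in spans:
        block = per_second.values[start:stop]
        n_blocks = len(block) // it
        for b in range(n_blocks):
            src = sec_samples[start + b * it]
            samples.append(
                SampleRecord(
                    entry=entry,
                    window_start=src.window_start,
                    integration_time=float(it),
                    labels=dict(src.labels),
                )
            )
            rows.append(block[b * it : (b + 1) * it].mean(axis=0))
    return FeatureMatrix(
        np.vstack(rows), samples, list(per_second.dim_names),
        scaling_params=per_second.scaling_params,
        pruned_dims=list(per_second.pruned_dims),
    )


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = _time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.1f s", name, dt)
            else:
                logger.error("stage %s: failed after %.1f s", name, dt)
            return False

    return _Timer()


def run(
    config: RunConfig,
    campaign_metadata: Path | str,
    audio_root: Path | str | None = None,
    out_path: Path | str | None = None,
    adapter: EmbeddingAdapter | None = None,
) -> ResultsBundle:
    """Execute the full pipeline on a campaign and assemble the results bundle.

    Stage errors propagate with the stage name in the log; the bundle file is
    only written once every section has been computed (no partial bundles).
    """
    with _stage("campaign_io"):
        entries = read_campaign(campaign_metadata, audio_root)
        label_names = list(entries[0].labels)

    with _stage("features"):
        features = build_features(entries, config, adapter)

    with _stage("ensemble"):
        ens = run_ensemble(
            features,
            method=config.projection,
            n_components=config.n_components,
            n_repeats=config.n_repeats,
            base_seed=config.base_seed,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
        )

    with _stage("labels"):
        labels = {name: label_from_samples(features.samples, name) for name in label_names}
        if len(label_names) > 1:
            composite = label_from_samples(features.samples, label_names)
            labels[composite.name] = composite

    with _stage("silhouettes"):
        silhouettes: dict[str, SilhouetteMatrix] = {}
        for name, lab in labels.items():
            counts = [np.sum(lab.values == c) for c in lab.categories]
            if lab.n_categories >= 2 and min(counts) >= 2:
                silhouettes[name] = silhouette_matrix(ens.avg_distance, lab)
            else:
                warnings.warn(f"skipping silhouette matrix for label {name!r}")

    with _stage("clusters"):
        clusters: dict[str, ClusterAssignment] = {}
        contingencies: dict[str, dict[str, ContingencyMatrix]] = {}
        for method in config.cluster_methods:
            assignment = cluster(
                ens.avg_distance,
                min_cluster_size=config.min_cluster_size,
                method=method,
                min_samples=config.min_samples,
            )
            clusters[method] = assignment
            contingencies[method] = {
                name: contingency(assignment, lab) for name, lab in labels.items()
            }

    with _stage("trajectories"):
        trajectories: dict[str, dict[str, TrajectorySeries]] = {}
        if config.group_label in labels and config.replicate_label in labels:
            for group in labels[config.group_label].categories:
                trajectories[group] = relative_trajectory(
                    ens,
                    features.samples,
                    config.group_label,
                    group,
                    config.replicate_label,
                    k=config.trajectory_k,
                )

    with _stage("diagnostics"):
        conv = convergence(ens) if ens.n_repeats >= 2 else None
        topo = topology_scores(
            features,
            ens.embeddings[0],
            k=min(config.diagnostics_k, features.n_samples - 1),
            n_triplets=config.diagnostics_triplets,
            seed=config.base_seed,
        )

    bundle = ResultsBundle(
        config=config,
        features=features,
        ensemble=ens,
        labels=labels,
        silhouettes=silhouettes,
        clusters=clusters,
        contingencies=contingencies,
        trajectories=trajectories,
        convergence=conv,
        topology=topo,
    )
    if out_path is not None:
        with _stage("save"):
            bundle.save(out_path)
    return bundle
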