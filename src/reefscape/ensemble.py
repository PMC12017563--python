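"""Ensemble low-dimensional projection and its stability diagnostics.

UMAP is stochastic: two runs with different seeds place points differently,
and any metric read off a single embedding inherits that noise. The remedy
used throughout this package is to repeat the projection N times with seeds
``base_seed + r``, compute the pairwise Euclidean distance matrix of each
repeat (the projection space is Euclidean), and average the matrices
elementwise. The averaged matrix is the substrate for the silhouette,
clustering and trajectory analyses.

Diagnostics:

* ``convergence`` — relative mean/max absolute differences between
  consecutive running-average distance matrices (the running mean of i.i.d.
  bounded matrices converges as 1/sqrt(n) by the CLT), plus the IQM
  distance-contrast series;
* ``iqm`` — interquartile range of the pairwise distances divided by their
  median, a scale-free measure of distance contrast;
* ``dlp`` / ``rta`` — local (shared k-nearest-neighbour fraction) and global
  (random triplet ordering agreement) topology preservation between the
  high-dimensional features and a low-dimensional embedding.

The "relative" normalization of the convergence differences divides by the
mean off-diagonal entry of the previous running average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .features import FeatureMatrix

__all__ = [
    "ProjectionEnsemble",
    "ConvergenceSeries",
    "TopologyScores",
    "run_ensemble",
    "convergence",
    "iqm",
    "dlp",
    "rta",
    "topology_scores",
    "pca_project",
]


@dataclass
class ProjectionEnsemble:
    """N low-dimensional point sets plus their averaged distance matrix."""

    method: str  # "umap" or "pca"
    n_components: int
    seeds: list[int]
    embeddings: np.ndarray  # (n_repeats, n_samples, n_components)
    distance_matrices: np.ndarray  # (n_repeats, n_samples, n_samples)
    avg_distance: np.ndarray  # (n_samples, n_samples)
    params: dict = field(default_factory=dict)

    @property
    def n_repeats(self) -> int:
        return self.embeddings.shape[0]

    @property
    def n_samples(self) -> int:
        return self.embeddings.shape[1]

    @classmethod
    def from_point_sets(
        cls,
        point_sets: list[np.ndarray] | np.ndarray,
        method: str = "umap",
        seeds: list[int] | None = None,
        params: dict | None = None,
    ) -> "ProjectionEnsemble":
        """Assemble an ensemble from precomputed point sets (one per repeat)."""
        emb = np.asarray(point_sets, dtype=np.float64)
        if emb.ndim != 3:
            raise ValueError("point_sets must stack to (n_repeats, n_samples, dims)")
        dists = np.stack([squareform(pdist(e)) for e in emb])
        return cls(
            method=method,
            n_components=emb.shape[2],
            seeds=list(seeds) if seeds is not None else list(range(emb.shape[0])),
            embeddings=emb,
            distance_matrices=dists,
            avg_distance=dists.mean(axis=0),
            params=dict(params or {}),
        )


@dataclass
class ConvergenceSeries:
    """Stability of the running-average distance matrix as repeats accrue."""

    n: np.ndarray  # 2..N, index of the diff series
    rel_mean_abs_diff: np.ndarray
    rel_max_abs_diff: np.ndarray
    iqm: np.ndarray  # over running averages 1..N


@dataclass
class TopologyScores:
    dlp: float
    rta: float
    k_neighbors: int
    n_triplets: int
    seed: int


def run_ensemble(
    features: FeatureMatrix | np.ndarray,
    method: str = "umap",
    n_components: int = 3,
    n_repeats: int = 100,
    base_seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> ProjectionEnsemble:
    """Repeat the projection N times and average the distance matrices.

    Repeat ``r`` uses seed ``base_seed + r``, so identical configurations
    reproduce identical ensembles. For ``method="pca"`` the projection is
    deterministic and ``n_repeats`` is forced to 1. ``n_neighbors`` is
    clamped to ``n_samples - 1`` on small datasets (the effective value is
    recorded in ``params``).
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    n_samples = X.shape[0]
    if n_samples < n_components + 2:
        raise ValueError(
            f"need at least n_components + 2 = {n_components + 2} samples, got {n_samples}"
        )
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    if method == "pca":
        points, _ = pca_project(X, n_components)
        return ProjectionEnsemble.from_point_sets(
            points[None], method="pca", seeds=[base_seed], params={}
        )
    if method != "umap":
        raise ValueError(f"unknown projection method {method!r}")

    import umap  # deferred: importing umap JIT-compiles numba kernels

    eff_neighbors = max(2, min(n_neighbors, n_samples - 1))
    seeds = [base_seed + r for r in range(n_repeats)]
    embeddings = np.empty((n_repeats, n_samples, n_components))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_neighbors is larger than")
        warnings.filterwarnings("ignore", message="n_jobs value .* overridden")
        for r, seed in enumerate(seeds):
            reducer = umap.UMAP(
                n_components=n_components,
                n_neighbors=eff_neighbors,
                min_dist=min_dist,
                random_state=seed,
            )
            embeddings[r] = reducer.fit_transform(X)
    return ProjectionEnsemble.from_point_sets(
        embeddings,
        method="umap",
        seeds=seeds,
        params={"n_neighbors": eff_neighbors, "min_dist": min_dist},
    )


def _offdiag(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    return matrix[np.triu_indices(n, k=1)]


def iqm(distance_matrix: np.ndarray) -> float:
    """Interquartile range of the pairwise distances divided by their median.

    Computed over the strictly-upper-triangle entries; scale-free
    (``iqm(c * D) == iqm(D)`` for any ``c > 0``).
    """
    d = _offdiag(np.asarray(distance_matrix, dtype=np.float64))
    if d.size < 1:
        raise ValueError("need at least 2 samples")
    med = np.median(d)
    if med <= 0:
        raise ValueError("median pairwise distance is zero (all points coincident)")
    q1, q3 = np.quantile(d, [0.25, 0.75], method="linear")
    return float((q3 - q1) / med)


def convergence(ensemble: ProjectionEnsemble) -> ConvergenceSeries:
    """Running-average stability of the ensemble's distance matrices.

    For each n >= 2, compares the running average over the first n repeats
    with the one over the first n-1, normalizing both the mean and the max
    absolute elementwise difference by the mean off-diagonal entry of the
    previous running average. Also returns the IQM of every running average.
    """
    mats = ensemble.distance_matrices
    n_repeats = mats.shape[0]
    running = np.cumsum(mats, axis=0) / np.arange(1, n_repeats + 1)[:, None, None]
    iqms = np.array([iqm(m) for m in running])
    rel_mean = np.empty(max(n_repeats - 1, 0))
    rel_max = np.empty(max(n_repeats - 1, 0))
    for i in range(1, n_repeats):
        diff = np.abs(_offdiag(running[i]) - _offdiag(running[i - 1]))
        denom = _offdiag(running[i - 1]).mean()
        rel_mean[i - 1] = diff.mean() / denom
        rel_max[i - 1] = diff.max() / denom
    return ConvergenceSeries(
        n=np.arange(2, n_repeats + 1),
        rel_mean_abs_diff=rel_mean,
        rel_max_abs_diff=rel_max,
        iqm=iqms,
    )


def _knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbours of each point, self excluded.

    Uses the full pairwise distance matrix (the package operates at sample
    counts where n^2 memory is cheap), which keeps k = n - 1 valid and the
    ordering deterministic.
    """
    D = squareform(pdist(np.asarray(X, dtype=np.float64)))
    np.fill_diagonal(D, np.inf)
    return np.argsort(D, axis=1, kind="stable")[:, :k]


def dlp(
    high_features: FeatureMatrix | np.ndarray,
    low_points: np.ndarray,
    k: int,
) -> float:
    """Degree of Local Preservation: mean shared-kNN fraction.

    For each sample, the fraction of its k nearest neighbours (Euclidean) in
    the high-dimensional feature space that are also among its k nearest
    neighbours in the low-dimensional embedding, averaged over samples.
    """
    X = high_features.values if isinstance(high_features, FeatureMatrix) else np.asarray(high_features)
    Y = np.asarray(low_points)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n_samples, got k={k}, n={n}")
    hi = _knn_indices(X, k)
    lo = _knn_indices(Y, k)
    shared = [len(set(hi[i]) & set(lo[i])) for i in range(n)]
    return float(np.mean(shared) / k)


def rta(
    high_features: FeatureMatrix | np.ndarray,
    low_points: np.ndarray,
    n_triplets: int = 50_000,
    seed: int = 0,
) -> float:
    """Random Triplet Accuracy: fraction of triplets with preserved ordering.

    Samples ``n_triplets`` anchored triplets (i; j, k) with distinct
    members uniformly at random and reports the fraction for which
    ``sign(d(i,j) - d(i,k))`` agrees between the high- and low-dimensional
    spaces. Deterministic given the seed.
    """
    X = high_features.values if isinstance(high_features, FeatureMatrix) else np.asarray(high_features)
    Y = np.asarray(low_points)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_triplets)
    j = rng.integers(0, n, size=n_triplets)
    k = rng.integers(0, n, size=n_triplets)
    bad = (i == j) | (i == k) | (j == k)
    while bad.any():
        j[bad] = rng.integers(0, n, size=int(bad.sum()))
        k[bad] = rng.integers(0, n, size=int(bad.sum()))
        bad = (i == j) | (i == k) | (j == k)

    def _d(A: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.linalg.norm(A[a] - A[b], axis=1)

    sign_hi = np.sign(_d(X, i, j) - _d(X, i, k))
    sign_lo = np.sign(_d(Y, i, j) - _d(Y, i, k))
    return float(np.mean(sign_hi == sign_lo))


def topology_scores(
    high_features: FeatureMatrix | np.ndarray,
    low_points: np.ndarray,
    k: int = 100,
    n_triplets: int = 50_000,
    seed: int = 0,
) -> TopologyScores:
    """Convenience bundle of DLP and RTA with their parameters recorded."""
    X = high_features.values if isinstance(high_features, FeatureMatrix) else np.asarray(high_features)
    k_eff = min(k, X.shape[0] - 1)
    return TopologyScores(
        dlp=dlp(high_features, low_points, k_eff),
        rta=rta(high_features, low_points, n_triplets, seed),
        k_neighbors=k_eff,
        n_triplets=n_triplets,
        seed=seed,
    )


def pca_project(
    features: FeatureMatrix | np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PCA projection with a fixed sign convention.

    Each principal axis is flipped, if needed, so that its largest-magnitude
    loading is positive; axes are then reproducible across runs. Returns the
    projected points and the explained-variance fractions (non-increasing).
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    n_samples, n_dims = X.shape
    if n_components > min(n_samples - 1, n_dims):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples - 1, n_dims) = "
            f"{min(n_samples - 1, n_dims)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    points = pca.fit_transform(X)
    comps = pca.components_
    flip = np.sign(comps[np.arange(n_components), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return points * flip, pca.explained_variance_ratio_.copy()
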