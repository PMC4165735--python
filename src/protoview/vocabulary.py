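"""Visual vocabulary: k-means codebook training and word quantization.

Descriptors pooled across all views of the training models are clustered
with k-means (k-means++ initialization, Lloyd iterations); the cluster
barycenters are the visual words, and the number of clusters is the
codebook size.  Assignment of a descriptor to its word is an exhaustive
linear search for the nearest centroid — the codebook sizes used here
(hundreds to a few thousand) keep that cheap and exact.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "Codebook",
    "sample_training_features",
    "train_codebook",
    "quantize",
    "save_codebook",
    "load_codebook",
]

CODEBOOK_FORMAT_VERSION = 1
DEFAULT_K = 3000
DEFAULT_TRAINING_CAP = 100_000


@dataclass(frozen=True)
class Codebook:
    """k visual words: the centroid matrix plus training metadata."""

    centroids: np.ndarray  # (k, 64)
    seed: int
    n_iter: int
    inertia: float

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        if c.ndim != 2 or c.shape[0] < 2:
            raise ValueError("a codebook needs at least 2 centroids")
        if not np.all(np.isfinite(c)):
            raise ValueError("centroids must be finite")
        object.__setattr__(self, "centroids", c)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]


def sample_training_features(
    features: np.ndarray, max_count: int, seed: int
) -> np.ndarray:
    """Uniform subsample without replacement of descriptor rows.

    Returns all rows in their original order when ``max_count`` covers the
    pool; otherwise a seed-reproducible subset (in draw order).
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] == 0:
        raise DataError("empty feature set")
    if features.shape[0] <= max_count:
        return features
    rng = np.random.default_rng(seed)
    idx = rng.choice(features.shape[0], size=max_count, replace=False)
    return features[idx]


def train_codebook(
    features: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> Codebook:
    """Cluster descriptors into k visual words (Lloyd + k-means++).

    Empty clusters are re-seeded by the implementation at the points
    contributing most to inertia, so the returned codebook always has
    exactly k words.
    """
    features = np.asarray(features, dtype=float)
    if k < 2:
        raise ParameterError("codebook size k must be >= 2")
    if features.shape[0] < k:
        raise ParameterError(
            f"need at least k={k} training descriptors, got {features.shape[0]}"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        algorithm="lloyd",
    ).fit(features)
    return Codebook(
        centroids=km.cluster_centers_.astype(float),
        seed=seed,
        n_iter=int(km.n_iter_),
        inertia=float(km.inertia_),
    )


def quantize(descriptor: np.ndarray, codebook: Codebook) -> int:
    """Nearest-centroid word index in [1, k] by exhaustive linear search.

    Ties are broken toward the lowest index.
    """
    d = np.asarray(descriptor, dtype=float)
    dists = np.linalg.norm(codebook.centroids - d, axis=1)
    return int(np.argmin(dists)) + 1


def quantize_batch(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Vectorized :func:`quantize` over rows; returns 1-based word indices."""
    d = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if d.shape[0] == 0:
        return np.empty(0, dtype=int)
    # ||d - c||^2 = ||d||^2 - 2 d.c + ||c||^2; argmin is tie-stable (first min)
    c = codebook.centroids
    d2 = (d * d).sum(axis=1)[:, None] - 2 * d @ c.T + (c * c).sum(axis=1)[None, :]
    return np.argmin(d2, axis=1) + 1


def save_codebook(codebook: Codebook, path: str | Path) -> Path:
    """Write a codebook to a versioned self-describing ``.npz`` container."""
    path = Path(path)
    np.savez(
        path,
        version=np.array([CODEBOOK_FORMAT_VERSION]),
        k=np.array([codebook.k]),
        dim=np.array([codebook.dim]),
        seed=np.array([codebook.seed]),
        n_iter=np.array([codebook.n_iter]),
        inertia=np.array([codebook.inertia]),
        centroids=codebook.centroids,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_codebook(path: str | Path) -> Codebook:
    """Read a codebook container; raises ``FormatError`` on a corrupt file."""
    try:
        with np.load(path) as data:
            version = int(data["version"][0])
            if version != CODEBOOK_FORMAT_VERSION:
                raise FormatError(f"unsupported codebook version {version}")
            centroids = data["centroids"]
            k = int(data["k"][0])
            if centroids.shape[0] != k:
                raise FormatError("codebook header disagrees with centroid matrix")
            return Codebook(
                centroids=centroids,
                seed=int(data["seed"][0]),
                n_iter=int(data["n_iter"][0]),
                inertia=float(data["inertia"][0]),
            )
    except (OSError, ValueError, KeyError, EOFError, zipfile.BadZipFile) as exc:
        raise FormatError(f"cannot read codebook file {path}: {exc}") from exc
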