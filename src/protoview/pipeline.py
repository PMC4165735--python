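"""High-level glue: run whole pipeline stages on in-memory databases.

These helpers chain the per-module operations (render -> extract ->
quantize -> histogram) for a collection of models, so the command-line
stages, the test-suite and scripted experiments share one code path.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .errors import DataError
from .features import SurfDescriptor, SurfParams, extract_features
from .multiview import render_all_views
from .retrieval import WordHistogram, model_histogram, view_histogram
from .structure_io import ProteinModel, normalize_model
from .vocabulary import (
    Codebook,
    quantize_batch,
    sample_training_features,
    train_codebook,
)

__all__ = [
    "extract_database_features",
    "pool_descriptors",
    "train_database_codebook",
    "build_model_histograms",
]

FeatureStore = dict[tuple[str, int], list[SurfDescriptor]]


def surf_params(config: PipelineConfig) -> SurfParams:
    return SurfParams(
        hessian_threshold=config.hessian_threshold,
        octaves=config.octaves,
        intervals_per_octave=config.intervals_per_octave,
        upright=config.upright,
    )


def extract_database_features(
    models: list[ProteinModel], config: PipelineConfig = PipelineConfig()
) -> FeatureStore:
    """Normalize, render 14 views and run SURF for every model."""
    params = surf_params(config)
    store: FeatureStore = {}
    for model in models:
        normalized = normalize_model(model)
        for view in render_all_views(normalized, size=config.image_size,
                                     fill=config.fill_factor):
            store[(model.model_id, view.view_id)] = extract_features(view, params)
    return store


def pool_descriptors(store: FeatureStore, model_ids=None) -> np.ndarray:
    """Stack all descriptors (optionally restricted to some models) row-wise."""
    rows = [
        d.values
        for (model_id, _), descs in sorted(store.items())
        for d in descs
        if model_ids is None or model_id in model_ids
    ]
    if not rows:
        raise DataError("no descriptors in the feature store")
    return np.array(rows)


def train_database_codebook(
    store: FeatureStore,
    config: PipelineConfig = PipelineConfig(),
    model_ids=None,
    k: int | None = None,
) -> Codebook:
    """Pool (a subset of) database descriptors, subsample, and run k-means."""
    pool = pool_descriptors(store, model_ids)
    pool = sample_training_features(pool, config.training_cap, config.seed)
    return train_codebook(pool, k if k is not None else config.codebook_k,
                          seed=config.seed)


def build_model_histograms(
    store: FeatureStore,
    codebook: Codebook,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, WordHistogram]:
    """Quantize every view's descriptors and combine into model histograms.

    With ``combination="sum"`` (default) the 14 view count-histograms are
    summed into one k-vector; ``"concat"`` joins them into a 14k-vector
    before smoothing and normalization.
    """
    per_model: dict[str, list[WordHistogram]] = {}
    for (model_id, view_id), descs in sorted(store.items()):
        if descs:
            mat = np.array([d.values for d in descs])
            words = quantize_batch(mat, codebook)
        else:
            words = np.empty(0, dtype=int)
        hist = view_histogram(words, codebook.k, owner=model_id, view_id=view_id)
        per_model.setdefault(model_id, []).append(hist)

    database: dict[str, WordHistogram] = {}
    for model_id, hists in per_model.items():
        if config.combination == "concat":
            joined = np.concatenate([h.bins for h in hists])
            merged = [WordHistogram(bins=joined, owner=model_id)]
        else:
            merged = hists
        database[model_id] = model_histogram(
            merged, epsilon=config.epsilon, owner=model_id
        )
    return database
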