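"""Word histograms, histogram divergence, ranking and retrieval evaluation.

Each view becomes a k-bin visual-word count histogram; a model's feature
vector is the bin-wise sum of its 14 view histograms, Laplace-smoothed
(add-epsilon, so every bin is strictly positive as the logarithm requires)
and L1-normalized.  Two models are compared with the symmetric divergence

    D(x, y) = sum_i (y_i - x_i) * ln(y_i / x_i),

which is the Jeffreys combination of the forward and reverse
Kullback-Leibler divergences: every term is non-negative and D vanishes
iff x = y.  The one-sided (asymmetric) Kullback-Leibler form
sum_i x_i ln(x_i / y_i) is available behind a flag for comparison.

Retrieval ranks all database models by ascending divergence from the
query; classification takes the top-ranked non-self entry's label
(leave-query-out nearest neighbor).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .errors import ContractError, DataError, DegenerateModelError

__all__ = [
    "WordHistogram",
    "RankedList",
    "view_histogram",
    "model_histogram",
    "kld",
    "retrieve",
    "nearest_neighbor_accuracy",
    "precision_recall",
    "roc_auc",
    "save_histograms",
    "load_histograms",
]

DEFAULT_EPSILON = 1.0  # Laplace add-one smoothing on raw counts
RECALL_LEVELS = np.linspace(0.0, 1.0, 11)


@dataclass(frozen=True)
class WordHistogram:
    """A k-bin visual-word histogram.

    Raw per-view histograms hold counts; combined model histograms are
    smoothed (all bins > 0) and L1-normalized (``smoothed=True``).
    """

    bins: np.ndarray
    owner: str
    view_id: int | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        if b.ndim != 1 or np.any(b < 0):
            raise ValueError("histogram bins must be a non-negative vector")
        if self.smoothed:
            if abs(b.sum() - 1.0) > 1e-9:
                raise ValueError("smoothed histogram must sum to 1")
            if np.any(b <= 0):
                raise ValueError("smoothed histogram must be strictly positive")
        object.__setattr__(self, "bins", b)

    @property
    def k(self) -> int:
        return self.bins.shape[0]

    @property
    def is_empty(self) -> bool:
        return bool(self.bins.sum() == 0)


@dataclass(frozen=True)
class RankedList:
    """Database models ordered by ascending divergence from the query."""

    query: str
    entries: tuple[tuple[str, float], ...]


def view_histogram(words, k: int, owner: str = "", view_id: int | None = None) -> WordHistogram:
    """Raw count histogram of 1-based word indices; empty input is allowed
    and yields an all-zero histogram."""
    words = np.asarray(list(words), dtype=int)
    if words.size and (words.min() < 1 or words.max() > k):
        raise ContractError("word index out of range [1, k]")
    bins = np.bincount(words - 1 if words.size else words, minlength=k)[:k]
    return WordHistogram(bins=bins.astype(float), owner=owner, view_id=view_id)


def model_histogram(
    view_histograms, epsilon: float = DEFAULT_EPSILON, owner: str | None = None
) -> WordHistogram:
    """Combine per-view count histograms into the model's feature vector.

    Counts are summed bin-wise across views, smoothed by adding ``epsilon``
    to every bin, and L1-normalized; the result is strictly positive as
    required by the divergence's logarithm.
    """
    hists = list(view_histograms)
    if not hists:
        raise ContractError("need at least one view histogram")
    ks = {h.k for h in hists}
    if len(ks) != 1:
        raise ContractError("view histograms must share the codebook size k")
    total = np.sum([h.bins for h in hists], axis=0)
    if total.sum() == 0:
        raise DegenerateModelError("all views are empty; no visual words found")
    smoothed = total + epsilon
    smoothed = smoothed / smoothed.sum()
    return WordHistogram(
        bins=smoothed,
        owner=owner if owner is not None else hists[0].owner,
        smoothed=True,
    )


def kld(x: WordHistogram, y: WordHistogram, symmetric: bool = True) -> float:
    """Histogram divergence D(x, y) = sum (y_i - x_i) ln(y_i / x_i).

    The default symmetric form is non-negative with D(x, x) = 0.  With
    ``symmetric=False`` the one-sided Kullback-Leibler divergence
    sum x_i ln(x_i / y_i) is computed instead.  Both require strictly
    positive bins, which smoothing guarantees.
    """
    if x.k != y.k:
        raise ContractError("histograms must share k")
    xb, yb = x.bins, y.bins
    if np.any(xb <= 0) or np.any(yb <= 0):
        raise ContractError("divergence needs strictly positive bins; smooth first")
    log_ratio = np.log(yb / xb)
    if symmetric:
        return float(np.sum((yb - xb) * log_ratio))
    return float(-np.sum(xb * log_ratio))


def retrieve(query: WordHistogram, database: dict[str, WordHistogram],
             symmetric: bool = True) -> RankedList:
    """Score every database model against the query and sort ascending.

    Ties are broken by model identifier so rankings are deterministic.
    """
    if not database:
        raise DataError("empty database")
    scored = sorted(
        ((kld(query, hist, symmetric=symmetric), model_id)
         for model_id, hist in database.items()),
        key=lambda t: (t[0], t[1]),
    )
    return RankedList(query=query.owner, entries=tuple((m, d) for d, m in scored))


def nearest_neighbor_accuracy(
    database: dict[str, WordHistogram],
    labels: dict[str, str],
    leave_query_out: bool = True,
    symmetric: bool = True,
) -> float:
    """Fraction of queries whose nearest neighbor shares the query's label.

    With ``leave_query_out`` (the default) the query itself is removed from
    its ranked list, so trivial self-matches at distance zero do not count;
    a query whose class has no other member is then counted as incorrect.
    """
    if not database:
        raise DataError("empty database")
    missing = [m for m in database if m not in labels]
    if missing:
        raise DataError(f"unlabeled models: {missing[:5]}")
    correct = 0
    for model_id, hist in database.items():
        ranked = retrieve(hist, database, symmetric=symmetric)
        for other_id, _ in ranked.entries:
            if leave_query_out and other_id == model_id:
                continue
            correct += labels[other_id] == labels[model_id]
            break
    return correct / len(database)


def precision_recall(
    database: dict[str, WordHistogram],
    labels: dict[str, str],
    symmetric: bool = True,
) -> np.ndarray:
    """11-point interpolated precision averaged over all queries.

    Every model queries the rest of the database (leave-query-out);
    relevance means sharing the query's label.  Returns the mean
    interpolated precision at recall 0.0, 0.1, ..., 1.0; the curve is
    non-increasing by construction.
    """
    if not database:
        raise DataError("empty database")
    curves = []
    for model_id, hist in database.items():
        ranked = retrieve(hist, database, symmetric=symmetric)
        rel = np.array(
            [labels[m] == labels[model_id] for m, _ in ranked.entries if m != model_id],
            dtype=bool,
        )
        n_rel = int(rel.sum())
        if n_rel == 0:
            continue
        hits = np.cumsum(rel)
        prec = hits / np.arange(1, rel.size + 1)
        recall = hits / n_rel
        interp = np.array(
            [prec[recall >= level].max() if np.any(recall >= level) else 0.0
             for level in RECALL_LEVELS]
        )
        curves.append(np.maximum.accumulate(interp[::-1])[::-1])
    if not curves:
        raise DataError("no query has a same-label partner")
    return np.mean(curves, axis=0)


def roc_auc(ranked: RankedList, labels: dict[str, str], query_label: str,
            exclude: str | None = None) -> float:
    """Rank-based AUC of one ranked list.

    The probability that a relevant (same-label) entry outranks an
    irrelevant one, with ties credited 0.5 — the Wilcoxon/Mann-Whitney
    statistic on the divergence scores.
    """
    entries = [(m, d) for m, d in ranked.entries if m != exclude]
    rel = np.array([labels[m] == query_label for m, _ in entries], dtype=bool)
    n_pos, n_neg = int(rel.sum()), int((~rel).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined without both relevant and irrelevant entries")
    dist = np.array([d for _, d in entries])
    ranks = rankdata(dist)  # smaller distance = better; ties share mid-ranks
    auc = (np.sum(ranks[~rel]) - n_neg * (n_neg + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def mean_roc_auc(
    database: dict[str, WordHistogram],
    labels: dict[str, str],
    symmetric: bool = True,
) -> float:
    """Mean leave-query-out AUC over all queries with a defined AUC."""
    aucs = []
    for model_id, hist in database.items():
        ranked = retrieve(hist, database, symmetric=symmetric)
        try:
            aucs.append(roc_auc(ranked, labels, labels[model_id], exclude=model_id))
        except DataError:
            continue
    if not aucs:
        raise DataError("AUC undefined for every query")
    return float(np.mean(aucs))


def save_histograms(
    database: dict[str, WordHistogram], path: str | Path, k: int,
    epsilon: float, combination: str = "sum",
) -> None:
    """Persist the model-histogram store with its header metadata."""
    ids = sorted(database)
    matrix = np.array([database[m].bins for m in ids])
    np.savez(
        path,
        ids=np.array(ids),
        matrix=matrix,
        k=np.array([k]),
        epsilon=np.array([epsilon]),
        combination=np.array([combination]),
    )


def load_histograms(path: str | Path) -> tuple[dict[str, WordHistogram], dict]:
    """Inverse of :func:`save_histograms`; returns (database, metadata)."""
    with np.load(path, allow_pickle=False) as data:
        ids = [str(s) for s in data["ids"]]
        matrix = data["matrix"]
        meta = {
            "k": int(data["k"][0]),
            "epsilon": float(data["epsilon"][0]),
            "combination": str(data["combination"][0]),
        }
    database = {
        mid: WordHistogram(bins=matrix[i], owner=mid, smoothed=True)
        for i, mid in enumerate(ids)
    }
    return database, meta
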