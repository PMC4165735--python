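import math

import numpy as np
import pytest

from protoview.errors import ContractError, DataError, DegenerateModelError
from protoview.retrieval import (
    RankedList,
    WordHistogram,
    kld,
    mean_roc_auc,
    model_histogram,
    nearest_neighbor_accuracy,
    precision_recall,
    retrieve,
    roc_auc,
    view_histogram,
)


def random_histogram(rng, k=16, owner="h"):
    bins = rng.random(k) + 1e-3
    return WordHistogram(bins=bins / bins.sum(), owner=owner, smoothed=True)


def kld_oracle(x, y):
    """Independent term-by-term evaluation of sum (y_i - x_i) ln(y_i / x_i)."""
    total = 0.0
    for xi, yi in zip(x, y):
        total += (yi - xi) * math.log(yi / xi)
    return total


class TestHistograms:
    def test_view_histogram_counts_words(self):
        h = view_histogram([1, 1, 3], k=4)
        np.testing.assert_array_equal(h.bins, [2, 0, 1, 0])
        assert h.bins.sum() == 3

    def test_empty_view_flagged(self):
        h = view_histogram([], k=4)
        assert h.is_empty
        np.testing.assert_array_equal(h.bins, [0, 0, 0, 0])

    def test_word_conservation(self):
        rng = np.random.default_rng(0)
        words = rng.integers(1, 11, size=137)
        assert view_histogram(words, k=10).bins.sum() == 137

    def test_out_of_range_word_rejected(self):
        with pytest.raises(ContractError):
            view_histogram([0, 1], k=4)
        with pytest.raises(ContractError):
            view_histogram([5], k=4)

    def test_model_histogram_hand_example(self):
        views = [
            view_histogram([1, 1, 2], k=2),
            view_histogram([1], k=2),
        ]  # summed counts (3, 1)
        h = model_histogram(views, epsilon=0.5)
        np.testing.assert_allclose(h.bins, [0.7, 0.3], atol=1e-12)

    def test_identical_views_normalize_like_a_single_view(self):
        one = [view_histogram([1, 2, 2, 4], k=5)]
        fourteen = [view_histogram([1, 2, 2, 4], k=5) for _ in range(14)]
        # smoothing scale must match the count scale for exact invariance
        a = model_histogram(one, epsilon=1.0)
        b = model_histogram(fourteen, epsilon=14.0)
        np.testing.assert_allclose(a.bins, b.bins, atol=1e-12)

    def test_count_scale_invariance(self):
        views = [view_histogram([1, 1, 2, 3], k=4) for _ in range(14)]
        scaled = [
            WordHistogram(bins=v.bins * 5, owner=v.owner, view_id=v.view_id) for v in views
        ]
        a = model_histogram(views, epsilon=1.0)
        b = model_histogram(scaled, epsilon=5.0)
        np.testing.assert_allclose(a.bins, b.bins, atol=1e-12)

    def test_model_histogram_sums_to_one_and_is_positive(self):
        rng = np.random.default_rng(1)
        views = [view_histogram(rng.integers(1, 33, size=20), k=32) for _ in range(14)]
        h = model_histogram(views)
        assert h.bins.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.bins > 0)

    def test_all_empty_views_rejected(self):
        with pytest.raises(DegenerateModelError):
            model_histogram([view_histogram([], k=4) for _ in range(14)])


class TestDivergence:
    def test_self_divergence_is_zero(self):
        h = random_histogram(np.random.default_rng(2))
        assert kld(h, h) == 0.0

    def test_hand_computed_value(self):
        x = WordHistogram(bins=np.array([0.5, 0.5]), owner="x", smoothed=True)
        y = WordHistogram(bins=np.array([0.25, 0.75]), owner="y", smoothed=True)
        expected = (-0.25) * math.log(0.5) + 0.25 * math.log(1.5)
        assert kld(x, y) == pytest.approx(expected, abs=1e-12)
        assert kld(x, y) == pytest.approx(0.27465, abs=5e-6)

    def test_oracle_equivalence_nonnegativity_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            x = random_histogram(rng)
            y = random_histogram(rng)
            d = kld(x, y)
            assert d == pytest.approx(kld_oracle(x.bins, y.bins), abs=1e-12)
            assert d >= 0
            assert kld(y, x) == pytest.approx(d, abs=1e-12)

    def test_asymmetric_mode_is_one_sided_kl(self):
        rng = np.random.default_rng(4)
        x, y = random_histogram(rng), random_histogram(rng)
        forward = float(np.sum(x.bins * np.log(x.bins / y.bins)))
        assert kld(x, y, symmetric=False) == pytest.approx(forward, abs=1e-12)
        # the symmetric printed form is the Jeffreys sum of both directions
        assert kld(x, y) == pytest.approx(
            kld(x, y, symmetric=False) + kld(y, x, symmetric=False), abs=1e-12
        )

    def test_zero_bins_rejected(self):
        raw = WordHistogram(bins=np.array([1.0, 0.0, 2.0]), owner="raw")
        pos = WordHistogram(bins=np.array([0.2, 0.3, 0.5]), owner="p", smoothed=True)
        with pytest.raises(ContractError):
            kld(raw, pos)


class TestRetrieve:
    def test_query_in_database_ranks_itself_first(self):
        rng = np.random.default_rng(5)
        db = {f"m{i}": random_histogram(rng, owner=f"m{i}") for i in range(6)}
        ranked = retrieve(db["m3"], db)
        assert ranked.entries[0] == ("m3", 0.0)
        assert len(ranked.entries) == 6
        dists = [d for _, d in ranked.entries]
        assert dists == sorted(dists)

    def test_singleton_database(self):
        rng = np.random.default_rng(6)
        db = {"only": random_histogram(rng, owner="only")}
        q = random_histogram(rng, owner="q")
        assert retrieve(q, db).entries[0][0] == "only"

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(7)
        db = {f"m{i}": random_histogram(rng, owner=f"m{i}") for i in range(20)}
        q = random_histogram(rng, owner="q")
        ranked = retrieve(q, db)
        oracle = sorted(
            ((kld_oracle(q.bins, h.bins), mid) for mid, h in db.items()),
            key=lambda t: (t[0], t[1]),
        )
        assert [m for _, m in oracle] == [m for m, _ in ranked.entries]

    def test_empty_database_rejected(self):
        q = random_histogram(np.random.default_rng(8))
        with pytest.raises(DataError):
            retrieve(q, {})


def two_class_database(rng, n_per_class=8, k=16, spread=0.0):
    """Two well-separated classes of histograms, optionally noisy."""
    db, labels = {}, {}
    protos = [np.concatenate([np.ones(k // 2), np.full(k // 2, 1e-3)]),
              np.concatenate([np.full(k // 2, 1e-3), np.ones(k // 2)])]
    for ci, proto in enumerate(protos):
        for i in range(n_per_class):
            bins = proto + spread * rng.random(k)
            mid = f"c{ci}_{i}"
            db[mid] = WordHistogram(bins=bins / bins.sum(), owner=mid, smoothed=True)
            labels[mid] = f"class{ci}"
    return db, labels


class TestEvaluation:
    def test_perfectly_separated_classes_classify_perfectly(self):
        rng = np.random.default_rng(9)
        db, labels = two_class_database(rng, spread=0.01)
        assert nearest_neighbor_accuracy(db, labels) == 1.0
        np.testing.assert_allclose(precision_recall(db, labels), 1.0)
        assert mean_roc_auc(db, labels) == 1.0

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(10)
        db, labels = two_class_database(rng, n_per_class=10, spread=2.0)
        accs = []
        ids = sorted(labels)
        values = [labels[m] for m in ids]
        for _ in range(100):
            rng.shuffle(values)
            accs.append(nearest_neighbor_accuracy(db, dict(zip(ids, values))))
        # binomial chance level for 2 balanced classes
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_singleton_class_counts_as_incorrect(self):
        rng = np.random.default_rng(11)
        db, labels = two_class_database(rng, n_per_class=2, spread=0.01)
        lone = random_histogram(rng, owner="lone")
        db["lone"] = lone
        labels["lone"] = "unique"
        acc = nearest_neighbor_accuracy(db, labels)
        assert acc == pytest.approx(4 / 5)

    def test_unlabeled_model_rejected(self):
        rng = np.random.default_rng(12)
        db, labels = two_class_database(rng)
        del labels[next(iter(db))]
        with pytest.raises(DataError):
            nearest_neighbor_accuracy(db, labels)

    def test_interpolated_precision_is_non_increasing(self):
        rng = np.random.default_rng(13)
        db, labels = two_class_database(rng, n_per_class=10, spread=3.0)
        curve = precision_recall(db, labels)
        assert curve.shape == (11,)
        assert np.all(np.diff(curve) <= 1e-12)

    def test_roc_auc_extremes_and_chance(self):
        labels = {f"r{i}": "pos" for i in range(5)}
        labels.update({f"n{i}": "neg" for i in range(5)})
        perfect = RankedList(
            query="q",
            entries=tuple([(f"r{i}", float(i)) for i in range(5)]
                          + [(f"n{i}", 5.0 + i) for i in range(5)]),
        )
        assert roc_auc(perfect, labels, "pos") == 1.0
        reversed_ = RankedList(
            query="q",
            entries=tuple((m, float(i)) for i, (m, _) in enumerate(reversed(perfect.entries))),
        )
        assert roc_auc(reversed_, labels, "pos") == 0.0
        rng = np.random.default_rng(14)
        aucs = []
        for _ in range(1000):
            order = rng.permutation([f"r{i}" for i in range(5)] + [f"n{i}" for i in range(5)])
            ranked = RankedList(
                query="q", entries=tuple((m, float(i)) for i, m in enumerate(order))
            )
            aucs.append(roc_auc(ranked, labels, "pos"))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_degenerate_label_sets_rejected(self):
        labels = {"a": "x", "b": "x"}
        ranked = RankedList(query="q", entries=(("a", 0.1), ("b", 0.2)))
        with pytest.raises(DataError):
            roc_auc(ranked, labels, "x")

    def test_noisier_queries_drift_monotonically_away(self):
        """Expected divergence grows with the noise injected into a query."""
        rng = np.random.default_rng(15)
        base = random_histogram(rng, k=32)
        sigmas = [0.0, 0.05, 0.2, 0.8]
        means = []
        for sigma in sigmas:
            dists = []
            for _ in range(100):
                noisy = np.maximum(base.bins + sigma * rng.normal(size=32), 0) + 1e-6
                noisy = noisy / noisy.sum()
                h = WordHistogram(bins=noisy, owner="noisy", smoothed=True)
                dists.append(kld(base, h))
            means.append(np.mean(dists))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))
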