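"""Splits, RF grid search, KNN protocol vs brute force, metrics, repeated CV."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import accuracy_score, cohen_kappa_score
from sklearn.neighbors import KNeighborsClassifier

from soarclass import classify
from soarclass.classify import (CVSummary, KNNConfig, MinMaxNormalizer,
                                RFConfig, balanced_accuracy_from_rates,
                                confusion_metrics, knn_optimize_and_classify,
                                knn_predict, npv_from_rates, optimize_rf,
                                refinement_range, repeated_kfold,
                                rf_variable_importance, split_70_30)


def _blobs(rng, n_per=60, sep=4.0, n_feat=4):
    """Three well-separated Gaussian clusters with trailing noise features."""
    X, y = [], []
    for i, c in enumerate([0.0, sep, 2 * sep]):
        pts = rng.normal(c, 1.0, (n_per, n_feat))
        pts[:, 2:] = rng.normal(0.0, 1.0, (n_per, n_feat - 2))
        X.append(pts)
        y += [f"c{i}"] * n_per
    return np.vstack(X), np.array(y)


class TestSplit:
    def test_stratified_70_30(self):
        y = np.repeat(["a", "b", "c"], 100)
        tr, te = split_70_30(y, seed=3)
        assert len(tr) + len(te) == 300
        assert len(np.intersect1d(tr, te)) == 0
        for lab in "abc":
            frac = (y[tr] == lab).sum() / 100
            assert 0.69 <= frac <= 0.71

    def test_same_seed_same_split(self):
        y = np.repeat(["a", "b"], 50)
        assert np.array_equal(split_70_30(y, seed=5)[0],
                              split_70_30(y, seed=5)[0])

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            split_70_30(np.array(["a", "a", "b"]))


class TestOptimizeRf:
    def test_single_cell_grid_selected(self, rng):
        X, y = _blobs(rng)
        cfg = optimize_rf(X, y, RFConfig(ntree_grid=(50,), mtry_grid=(2,)))
        assert (cfg.selected_ntree, cfg.selected_mtry) == (50, 2)

    def test_selected_cell_minimizes_oob(self, rng):
        X, y = _blobs(rng)
        cfg = optimize_rf(X, y, RFConfig(ntree_grid=(30, 60),
                                         mtry_grid=(1, 2, 4), seed=0))
        surface = cfg.oob_error_surface
        best = surface["oob_error"].min()
        chosen = surface.loc[(surface["ntree"] == cfg.selected_ntree)
                             & (surface["mtry"] == cfg.selected_mtry),
                             "oob_error"].iloc[0]
        assert chosen == best

    def test_degenerate_training_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            optimize_rf(X, np.array(["a"] * 20))


class TestImportance:
    def test_planted_signal_outranks_noise(self, rng):
        X, y = _blobs(rng, n_per=80)
        clf = classify.fit_rf(X, y, 100, 2, seed=0, oob=False)
        imp = rf_variable_importance(clf, X, y,
                                     ["sig0", "sig1", "noise0", "noise1"],
                                     seed=0)
        assert set(imp["feature"]) == {"sig0", "sig1", "noise0", "noise1"}
        ranked = list(imp["feature"])
        assert ranked.index("sig0") < ranked.index("noise0")
        assert ranked.index("sig0") < ranked.index("noise1")


def _brute_knn(Xtr, ytr, Xq, k):
    """Exhaustive pairwise-distance vote, smallest class label on ties."""
    classes = np.array(sorted(set(ytr)))
    out = []
    for q in Xq:
        d = np.sqrt(((Xtr - q) ** 2).sum(axis=1))
        nearest = np.argsort(d, kind="stable")[:k]
        votes = {c: 0 for c in classes}
        for i in nearest:
            votes[ytr[i]] += 1
        top = max(votes.values())
        out.append(min(c for c, v in votes.items() if v == top))
    return np.array(out)


class TestKnn:
    def test_single_neighbor_returns_training_label(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.array(["a", "b", "c"] * 10)
        pred = knn_predict(X, y, X[[4, 17]], 1)
        assert list(pred) == [y[4], y[17]]

    def test_matches_bruteforce_oracle(self, rng):
        X = rng.standard_normal((200, 3))
        y = rng.choice(["flap", "sit", "soar"], 200)
        Q = rng.standard_normal((50, 3))
        for k in (1, 7):
            np.testing.assert_array_equal(knn_predict(X, y, Q, k),
                                          _brute_knn(X, y, Q, k))

    def test_k_exceeding_training_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError):
            knn_predict(X, np.array(list("ababa")), X, 6)

    def test_refinement_brackets_two_best(self):
        assert list(refinement_range(25, 30)) == [25, 26, 27, 28, 29, 30]
        assert list(refinement_range(30, 25)) == [25, 26, 27, 28, 29, 30]

    def test_selected_k_is_argmax_of_evaluated(self, rng):
        X, y = _blobs(rng, n_per=80, sep=2.0, n_feat=3)
        tr, te = split_70_30(y, seed=1)
        res = knn_optimize_and_classify(X[tr], y[tr], X[te], y[te],
                                        KNNConfig(k_coarse=(5, 10, 15, 20)))
        best = max(res.config.accuracy_by_k.values())
        assert res.config.accuracy_by_k[res.selected_k] == best
        ties = [k for k, a in res.config.accuracy_by_k.items() if a == best]
        assert res.selected_k == min(ties)
        acc = (res.predictions == y[te]).mean()
        assert acc == pytest.approx(best)

    def test_normalizer_fits_train_only_and_clips(self, rng):
        X = rng.uniform(0, 1, (50, 3))
        norm = MinMaxNormalizer().fit(X)
        Z = norm.transform(np.array([[10.0, -10.0, 0.5]]))
        assert Z[0, 0] == 1.5 and Z[0, 1] == -0.5
        with pytest.raises(ValueError):
            MinMaxNormalizer().fit(np.ones((5, 2)))


class TestConfusionMetrics:
    def test_matches_sklearn_accuracy_and_kappa(self, rng):
        y = rng.choice(list("abc"), 300)
        p = rng.choice(list("abc"), 300)
        rep = confusion_metrics(y, p)
        assert rep.overall_accuracy == pytest.approx(accuracy_score(y, p))
        assert rep.kappa == pytest.approx(cohen_kappa_score(y, p))

    def test_internal_identities(self, rng):
        y = rng.choice(list("abc"), 200)
        p = rng.choice(list("abc"), 200)
        rep = confusion_metrics(y, p)
        prevs = [d["prevalence"] for d in rep.per_class.values()]
        assert sum(prevs) == pytest.approx(1.0)
        for d in rep.per_class.values():
            assert d["balanced_accuracy"] == pytest.approx(
                0.5 * (d["sensitivity"] + d["specificity"]))
            for v in d.values():
                assert np.isnan(v) or 0.0 <= v <= 1.0

    def test_perfect_predictions(self):
        y = list("aabbcc")
        rep = confusion_metrics(y, y)
        assert rep.overall_accuracy == 1.0
        assert rep.kappa == pytest.approx(1.0)

    def test_zero_denominator_reported_missing(self):
        rep = confusion_metrics(["a", "a", "b"], ["a", "a", "a"])
        assert np.isnan(rep.per_class["b"]["ppv"])  # never predicted b
        assert rep.per_class["b"]["sensitivity"] == 0.0

    def test_rate_identities_from_bayes(self):
        assert balanced_accuracy_from_rates(0.8, 0.9) == pytest.approx(0.85)
        # consistency with counts: derive npv from an explicit matrix
        y = ["a"] * 40 + ["b"] * 60
        p = ["a"] * 30 + ["b"] * 10 + ["b"] * 55 + ["a"] * 5
        rep = confusion_metrics(y, p)
        d = rep.per_class["a"]
        assert npv_from_rates(d["sensitivity"], d["specificity"],
                              d["prevalence"]) == pytest.approx(d["npv"])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.permutations(["x", "y", "z"]))
def test_kappa_invariant_to_relabeling(perm):
    """Cohen's kappa is unchanged under any class-name permutation."""
    g = np.random.default_rng(7)
    y = g.choice(["x", "y", "z"], 150)
    p = g.choice(["x", "y", "z"], 150)
    mapping = dict(zip(["x", "y", "z"], perm))
    y2 = np.array([mapping[v] for v in y])
    p2 = np.array([mapping[v] for v in p])
    assert confusion_metrics(y2, p2).kappa == pytest.approx(
        confusion_metrics(y, p).kappa)


class TestRepeatedKfold:
    @staticmethod
    def _factory(seed):
        return KNeighborsClassifier(n_neighbors=1)

    def test_separable_data_zero_error(self, rng):
        X, y = _blobs(rng, n_per=40, sep=50.0)
        cv = repeated_kfold(X, y, self._factory, k=5, reps=2, seed=0)
        assert cv.mean == 0.0

    def test_shuffled_labels_hit_chance_level(self, rng):
        X = rng.standard_normal((300, 3))
        y = np.repeat(["a", "b", "c"], 100)
        cv = repeated_kfold(X, y, self._factory, k=5, reps=3, seed=1)
        assert cv.mean == pytest.approx(2.0 / 3.0, abs=0.08)

    def test_summary_ordering(self, rng):
        errors = rng.uniform(0, 1, 10)
        s = CVSummary(errors)
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max
        assert s.min <= s.mean <= s.max

    def test_too_few_items_rejected(self, rng):
        with pytest.raises(ValueError):
            repeated_kfold(rng.standard_normal((5, 2)),
                           np.array(list("ababa")), self._factory, k=10)
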