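"""Classification engines: splitting, LDA, bagged forest, evaluation, projection."""

import numpy as np
import pandas as pd
import pytest

from femtri.classify import (
    Dataset,
    SplitSpec,
    evaluate,
    fit_lda,
    fit_random_forest,
    importance,
    kfold_cv,
    load_lda,
    random_projection_2d,
    save_model,
    split,
)


def make_dataset(X, y, columns=None):
    X = np.asarray(X, dtype=float)
    columns = columns or [f"f{j}" for j in range(X.shape[1])]
    return Dataset(pd.DataFrame(X, columns=columns), pd.Series(np.asarray(y, dtype=str)))


def gaussian_blobs(rng, centers, n_per, sd=1.0):
    X = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    y = np.repeat([f"c{i}" for i in range(len(centers))], n_per)
    return make_dataset(X, y)


class TestSplit:
    def test_70_30_balanced(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (5, 5)], 5)
        train, test = split(ds, SplitSpec(seed=1))
        assert len(train) == 7 and len(test) == 3
        assert set(train.labels.unique()) == set(test.labels.unique()) == {"c0", "c1"}

    def test_deterministic_and_disjoint(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (5, 5)], 20)
        t1, e1 = split(ds, SplitSpec(seed=3))
        t2, e2 = split(ds, SplitSpec(seed=3))
        assert t1.features.equals(t2.features) and e1.features.equals(e2.features)
        assert set(t1.features.index).isdisjoint(e1.features.index)
        assert len(t1) + len(e1) == len(ds)

    def test_stratification_proportions(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (5, 5), (9, 0)], 30)
        train, _ = split(ds, SplitSpec(seed=0))
        counts = train.labels.value_counts()
        assert all(abs(c - 21) <= 1 for c in counts)

    def test_singleton_class_rejected(self, rng):
        ds = make_dataset([[0, 0], [1, 1], [5, 5]], ["a", "a", "b"])
        with pytest.raises(ValueError, match="b"):
            split(ds, SplitSpec(seed=0))


class TestLda:
    def test_toy_matches_hand_mahalanobis(self):
        # frozen brute-force Mahalanobis classification (pooled covariance,
        # equal priors) computed independently before the build
        train = make_dataset(
            [[0, 0], [1, 0], [0, 1], [3, 3], [4, 3], [3, 4]],
            ["a", "a", "a", "b", "b", "b"],
        )
        model = fit_lda(train)
        test = pd.DataFrame(
            [[0.5, 0.5], [2, 2], [3.5, 3.2], [1.4, 1.4], [1.8, 1.8]],
            columns=train.features.columns,
        )
        assert model.predict(test).tolist() == ["a", "b", "b", "a", "a"]

    def test_separable_is_perfect(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (20, 20)], 40, sd=1.0)
        train, test = split(ds, SplitSpec(seed=0))
        model = fit_lda(train)
        assert evaluate(model, test).overall_accuracy_pct == 100.0

    def test_permuted_labels_near_chance(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (4, 4)], 300)
        shuffled = Dataset(ds.features, pd.Series(rng.permutation(ds.labels.to_numpy())))
        train, test = split(shuffled, SplitSpec(seed=0))
        acc = evaluate(fit_lda(train), test).overall_accuracy_pct
        assert abs(acc - 50.0) < 10.0

    def test_schema_mismatch_rejected(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (5, 5)], 10)
        model = fit_lda(ds)
        bad = ds.features.rename(columns={"f0": "x0"})
        with pytest.raises(ValueError, match="schema"):
            model.predict(bad)

    def test_json_round_trip_preserves_decisions(self, rng, tmp_path):
        ds = gaussian_blobs(rng, [(0, 0), (3, 3), (6, 0)], 25)
        model = fit_lda(ds)
        save_model(model, tmp_path / "lda.json")
        clone = load_lda(tmp_path / "lda.json")
        probe = pd.DataFrame(rng.normal(3, 3, (50, 2)), columns=ds.features.columns)
        assert (clone.predict(probe) == model.predict(probe)).all()


class TestForest:
    def test_separable_oob_goes_to_zero(self, rng):
        X = np.concatenate([rng.uniform(0, 1, 120), rng.uniform(3, 4, 120)])[:, None]
        y = np.repeat(["lo", "hi"], 120)
        ds = make_dataset(X, y)
        model = fit_random_forest(ds, n_trees=50, seed=0)
        assert model.oob_error_pct < 2.0
        assert model.training_accuracy_pct == 100.0

    def test_seeded_refit_is_identical(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (2, 2), (4, 0)], 30)
        m1 = fit_random_forest(ds, n_trees=40, seed=9)
        m2 = fit_random_forest(ds, n_trees=40, seed=9)
        assert m1.oob_error_pct == m2.oob_error_pct
        probe = ds.features
        assert (m1.predict(probe) == m2.predict(probe)).all()
        assert np.array_equal(m1.oob_masks, m2.oob_masks)

    def test_single_class_rejected(self):
        ds = make_dataset([[0, 0], [1, 1]], ["a", "a"])
        with pytest.raises(ValueError, match="single-class"):
            fit_random_forest(ds, n_trees=5)

    def test_mtry_bounds(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (5, 5)], 10)
        with pytest.raises(ValueError):
            fit_random_forest(ds, n_trees=5, mtry=3)

    def test_vote_counts_cover_all_trees(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (5, 5)], 15)
        model = fit_random_forest(ds, n_trees=17, seed=2)
        votes = model._votes(ds.features.to_numpy())
        assert (votes.sum(axis=1) == 17).all()


class TestImportance:
    def test_informative_feature_ranks_first(self, rng):
        n = 150
        signal = np.concatenate([rng.normal(0, 1, n), rng.normal(3, 1, n)])
        noise = rng.normal(0, 1, (2 * n, 2))
        X = np.column_stack([noise[:, 0], signal, noise[:, 1]])
        y = np.repeat(["a", "b"], n)
        ds = make_dataset(X, y, columns=["noise1", "signal", "noise2"])
        model = fit_random_forest(ds, n_trees=60, seed=0)
        rep = importance(model, seed=0)
        assert rep.ranking("mda")[0] == "signal"
        assert rep.ranking("mdi")[0] == "signal"
        # pure-noise features sit at zero importance within permutation noise
        noise_mda = [rep.mda[list(rep.features).index(f)] for f in ("noise1", "noise2")]
        assert all(abs(v) < 0.02 for v in noise_mda)

    def test_mdi_normalised(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (3, 3)], 40)
        rep = importance(fit_random_forest(ds, n_trees=30, seed=1), seed=1)
        assert rep.mdi.sum() == pytest.approx(1.0, abs=1e-12)
        assert (rep.mdi >= 0).all()


class TestKfold:
    def test_separable_fold_accuracy(self, rng):
        ds = make_dataset(
            [[0], [0.1], [0.2], [0.3], [5], [5.1], [5.2], [5.3]],
            ["a", "a", "a", "a", "b", "b", "b", "b"],
        )
        mean, sd, folds = kfold_cv(ds, fit_lda, k=4, seed=0)
        assert mean == 100.0 and len(folds) == 4

    def test_deterministic_folds(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (3, 3)], 25)
        r1 = kfold_cv(ds, fit_lda, k=5, seed=4)
        r2 = kfold_cv(ds, fit_lda, k=5, seed=4)
        assert r1 == r2

    def test_k_exceeding_class_size(self, rng):
        ds = make_dataset([[0], [1], [5], [6]], ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="smallest class"):
            kfold_cv(ds, fit_lda, k=3)

    def test_cv_tracks_heldout_on_synthetic(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (2.5, 2.5)], 150)
        mean_cv, _, _ = kfold_cv(ds, fit_lda, k=5, seed=0)
        train, test = split(ds, SplitSpec(seed=1))
        heldout = evaluate(fit_lda(train), test).overall_accuracy_pct
        assert abs(mean_cv - heldout) < 8.0


class _ConstantModel:
    def __init__(self, label, class_names):
        self.label = label
        self.class_names = class_names

    def predict(self, features):
        return np.repeat(self.label, len(features))


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (30, 30)], 20)
        model = fit_lda(ds)
        rep = evaluate(model, ds)
        conf = rep.confusion.to_numpy()
        assert np.trace(conf) == conf.sum() == len(ds)
        assert rep.overall_accuracy_pct == 100.0
        assert (rep.per_class_accuracy_pct == 100.0).all()

    def test_constant_predictor_bookkeeping(self, rng):
        ds = gaussian_blobs(rng, [(0, 0), (5, 5), (9, 0)], 10)
        rep = evaluate(_ConstantModel("c1", ds.class_names), ds)
        assert rep.overall_accuracy_pct == pytest.approx(100 / 3, abs=0.1)
        assert rep.per_class_accuracy_pct["c1"] == 100.0
        assert rep.per_class_accuracy_pct["c0"] == 0.0
        # row sums equal per-class test counts; trace/total equals overall
        assert (rep.confusion.sum(axis=1) == 10).all()
        assert rep.one_vs_all.loc["c1", "recall_pct"] == 100.0
        assert rep.one_vs_all.loc["c1", "specificity_pct"] == 0.0


class TestRandomProjection:
    def test_deterministic_and_duplicates(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (20, 5)))
        X.iloc[7] = X.iloc[3]
        p1 = random_projection_2d(X, seed=5)
        p2 = random_projection_2d(X, seed=5)
        assert np.array_equal(p1, p2)
        assert np.allclose(p1[3], p1[7])
        assert np.linalg.matrix_rank(p1) == 2

    def test_distance_preservation_in_expectation(self, rng):
        X = rng.normal(0, 1, (12, 10))
        d_orig = np.linalg.norm(X[0] - X[1])
        ratios = []
        for seed in range(200):
            proj = random_projection_2d(pd.DataFrame(X), seed=seed)
            ratios.append((np.linalg.norm(proj[0] - proj[1]) / d_orig) ** 2)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)

    def test_needs_two_features(self):
        with pytest.raises(ValueError):
            random_projection_2d(pd.DataFrame({"x": [1.0, 2.0]}), seed=0)
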