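"""Classification engines and evaluation machinery.

Two classifiers drive all experiments:

* linear discriminant analysis (LDA) — group-specific means with a pooled
  within-group covariance; under equal priors prediction is minimum
  Mahalanobis distance.  Delegated to scikit-learn's well-tested solver.
* a bagged decision-tree ensemble (random forest) implemented here as an
  explicit bootstrap-aggregation loop over scikit-learn decision trees, so
  that out-of-bag (OOB) bookkeeping stays first-class: OOB error, OOB
  majority-vote predictions, and permutation importance (mean decrease in
  accuracy, MDA) computed tree-by-tree on each tree's own OOB samples.
  Mean decrease in impurity (MDI) is averaged over trees and normalised.

Also here: stratified 70/30 splitting, stratified k-fold cross-validation,
confusion-matrix evaluation with per-class (one-vs-all) accuracies, and the
Gaussian random projection used for 2D visualisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.random_projection import GaussianRandomProjection
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "Dataset",
    "SplitSpec",
    "LdaModel",
    "ForestModel",
    "EvalReport",
    "ImportanceReport",
    "split",
    "fit_lda",
    "fit_random_forest",
    "importance",
    "kfold_cv",
    "evaluate",
    "random_projection_2d",
    "save_model",
    "load_lda",
]


@dataclass
class Dataset:
    """Feature matrix with ordered columns plus a categorical label vector."""

    features: pd.DataFrame
    labels: pd.Series
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        if self.features.isna().any().any():
            raise ValueError("missing values in features")
        if not self.class_names:
            self.class_names = tuple(sorted(pd.unique(self.labels.astype(str))))

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def split(dataset: Dataset, spec: SplitSpec = SplitSpec()) -> tuple[Dataset, Dataset]:
    """Deterministic train/test partition; stratified by label by default.

    Under stratification every class needs >= 2 members so both parts can be
    populated.  Train and test are disjoint and jointly exhaustive.
    """
    y = dataset.labels.astype(str)
    if spec.stratified:
        counts = y.value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"stratified split needs >=2 members per class; offending: {bad}")
        strat = y
    else:
        strat = None
    idx_train, idx_test = train_test_split(
        np.arange(len(dataset)),
        train_size=spec.train_fraction,
        stratify=strat,
        random_state=spec.seed,
        shuffle=True,
    )
    idx_train.sort()
    idx_test.sort()
    return (
        Dataset(dataset.features.iloc[idx_train], y.iloc[idx_train], dataset.class_names),
        Dataset(dataset.features.iloc[idx_test], y.iloc[idx_test], dataset.class_names),
    )


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    """Fitted linear discriminant classifier."""

    estimator: LinearDiscriminantAnalysis
    class_names: tuple[str, ...]
    columns: tuple[str, ...]
    priors: str
    training_accuracy_pct: float

    model_kind: str = "lda"

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        _check_schema(self.columns, features)
        return self.estimator.predict(features.to_numpy(dtype=float)).astype(str)


def fit_lda(train: Dataset, priors: str = "equal") -> LdaModel:
    """Fit LDA with equal (default) or class-proportional priors.

    Equal priors match the chance-level convention (1/k for k classes);
    proportional priors weight by training frequencies.  A singular pooled
    covariance is handled by the SVD solver's implicit regularisation.
    """
    if priors not in ("equal", "proportional"):
        raise ValueError("priors must be 'equal' or 'proportional'")
    classes = train.class_names
    prior_vec = None
    if priors == "equal":
        prior_vec = np.full(len(classes), 1.0 / len(classes))
    est = LinearDiscriminantAnalysis(priors=prior_vec)
    X = train.features.to_numpy(dtype=float)
    y = train.labels.astype(str).to_numpy()
    est.fit(X, y)
    acc = float(np.mean(est.predict(X) == y)) * 100.0
    return LdaModel(
        estimator=est,
        class_names=classes,
        columns=tuple(train.features.columns),
        priors=priors,
        training_accuracy_pct=acc,
    )


# ---------------------------------------------------------------------------
# Bagged decision-tree ensemble
# ---------------------------------------------------------------------------

@dataclass
class ForestModel:
    """Bagged tree ensemble with stored bootstrap/OOB bookkeeping.

    ``oob_masks[t]`` flags the training rows absent from tree t's bootstrap;
    OOB predictions for each training row aggregate votes only from trees
    that left it out.  Ties in every majority vote break by ``class_names``
    order, deterministically.
    """

    trees: list[DecisionTreeClassifier]
    oob_masks: np.ndarray           # (n_trees, n_train) bool
    train_X: np.ndarray             # retained for OOB permutation importance
    train_y: np.ndarray
    class_names: tuple[str, ...]
    columns: tuple[str, ...]
    n_trees: int
    mtry: int
    seed: int
    training_accuracy_pct: float = 0.0
    oob_error_pct: float = float("nan")

    model_kind: str = "random_forest"

    def _votes(self, X: np.ndarray, tree_subset: Sequence[int] | None = None) -> np.ndarray:
        k = len(self.class_names)
        votes = np.zeros((len(X), k), dtype=np.int64)
        idx = range(len(self.trees)) if tree_subset is None else tree_subset
        class_index = {c: j for j, c in enumerate(self.class_names)}
        for t in idx:
            pred = self.trees[t].predict(X)
            for j, c in enumerate(self.class_names):
                votes[:, j] += pred == c
        return votes

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        _check_schema(self.columns, features)
        votes = self._votes(features.to_numpy(dtype=float))
        return np.asarray(self.class_names)[votes.argmax(axis=1)]

    def oob_predictions(self) -> np.ndarray:
        """Majority vote per training row over trees whose bootstrap excluded it.

        Rows never out-of-bag (possible for tiny ensembles) get the first
        class name; with default tree counts this is vanishingly rare.
        """
        n = len(self.train_y)
        k = len(self.class_names)
        votes = np.zeros((n, k), dtype=np.int64)
        for t, tree in enumerate(self.trees):
            mask = self.oob_masks[t]
            if not mask.any():
                continue
            pred = tree.predict(self.train_X[mask])
            for j, c in enumerate(self.class_names):
                votes[np.flatnonzero(mask)[pred == c], j] += 1
        return np.asarray(self.class_names)[votes.argmax(axis=1)]


def fit_random_forest(
    train: Dataset,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
    min_samples_leaf: int = 1,
) -> ForestModel:
    """Grow a bagged ensemble of CART trees with per-node feature subsampling.

    Each tree is fit on a bootstrap resample (with replacement, same size as
    the training set); at every node the best Gini split is chosen among a
    random subset of ``mtry`` features (default ceil(sqrt(p))).  Trees grow
    to purity by default.  The OOB error is the misclassification rate of
    the OOB majority-vote predictions.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = train.features.to_numpy(dtype=float)
    y = train.labels.astype(str).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training set is single-class; nothing to learn")
    p = X.shape[1]
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    if not (1 <= mtry <= p):
        raise ValueError(f"mtry must be in [1, {p}]")

    rng = np.random.default_rng(seed)
    n = len(y)
    trees: list[DecisionTreeClassifier] = []
    oob_masks = np.zeros((n_trees, n), dtype=bool)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob_masks[t] = ~np.isin(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)

    model = ForestModel(
        trees=trees, oob_masks=oob_masks, train_X=X, train_y=y,
        class_names=train.class_names, columns=tuple(train.features.columns),
        n_trees=n_trees, mtry=mtry, seed=seed,
    )
    model.training_accuracy_pct = float(np.mean(model.predict(train.features) == y)) * 100.0
    ever_oob = model.oob_masks.any(axis=0)
    if ever_oob.any():
        oob_pred = model.oob_predictions()
        model.oob_error_pct = float(np.mean(oob_pred[ever_oob] != y[ever_oob])) * 100.0
    return model


@dataclass(frozen=True)
class ImportanceReport:
    """Per-feature MDA (OOB permutation) and MDI (normalised impurity decrease)."""

    features: tuple[str, ...]
    mda: np.ndarray
    mdi: np.ndarray

    def ranking(self, measure: str = "mda") -> tuple[str, ...]:
        values = self.mda if measure == "mda" else self.mdi
        order = np.argsort(-values, kind="stable")
        return tuple(self.features[i] for i in order)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.features, "mda": self.mda, "mdi": self.mdi})


def importance(forest: ForestModel, seed: int = 0) -> ImportanceReport:
    """Variable importances from the fitted ensemble.

    MDA: for each tree, accuracy on its own OOB rows minus accuracy after
    permuting one feature among those rows, averaged over trees.  MDI: each
    tree's impurity-decrease attribution, averaged over the ensemble and
    normalised to sum 1.
    """
    rng = np.random.default_rng(seed)
    p = len(forest.columns)
    mda_sums = np.zeros(p)
    mda_counts = np.zeros(p)
    mdi = np.zeros(p)
    for t, tree in enumerate(forest.trees):
        mdi += tree.feature_importances_
        mask = forest.oob_masks[t]
        if not mask.any():
            continue
        X_oob = forest.train_X[mask]
        y_oob = forest.train_y[mask]
        base_acc = np.mean(tree.predict(X_oob) == y_oob)
        for j in range(p):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(len(X_perm)), j]
            perm_acc = np.mean(tree.predict(X_perm) == y_oob)
            mda_sums[j] += base_acc - perm_acc
            mda_counts[j] += 1
    mda = np.divide(mda_sums, mda_counts, out=np.zeros(p), where=mda_counts > 0)
    mdi /= len(forest.trees)
    total = mdi.sum()
    if total > 0:
        mdi = mdi / total
    return ImportanceReport(features=forest.columns, mda=mda, mdi=mdi)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix (rows=true, cols=predicted) with derived accuracies."""

    confusion: pd.DataFrame
    overall_accuracy_pct: float
    per_class_accuracy_pct: pd.Series      # recall per true class
    one_vs_all: pd.DataFrame               # per class: tp, fn, fp, tn, recall, specificity, ova accuracy


def evaluate(model, test: Dataset) -> EvalReport:
    """Confusion counts plus overall, per-class and one-vs-all accuracies.

    Per-class accuracy is recall (row-normalised diagonal).  The one-vs-all
    decomposition treats each class in turn as the positive against all
    remaining classes pooled.
    """
    y_true = test.labels.astype(str).to_numpy()
    y_pred = np.asarray(model.predict(test.features)).astype(str)
    classes = list(model.class_names)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    total = conf.to_numpy().sum()
    overall = 100.0 * np.trace(conf.to_numpy()) / total if total else float("nan")
    row_sums = conf.sum(axis=1)
    per_class = 100.0 * pd.Series(np.diag(conf), index=classes) / row_sums.replace(0, np.nan)

    ova_rows = []
    for c in classes:
        tp = int(conf.loc[c, c])
        fn = int(row_sums[c] - tp)
        fp = int(conf[c].sum() - tp)
        tn = int(total - tp - fn - fp)
        ova_rows.append({
            "class": c, "tp": tp, "fn": fn, "fp": fp, "tn": tn,
            "recall_pct": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
            "specificity_pct": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
            "ova_accuracy_pct": 100.0 * (tp + tn) / total if total else float("nan"),
        })
    return EvalReport(
        confusion=conf,
        overall_accuracy_pct=float(overall),
        per_class_accuracy_pct=per_class,
        one_vs_all=pd.DataFrame(ova_rows).set_index("class"),
    )


def kfold_cv(
    dataset: Dataset,
    fit_fn,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Stratified k-fold cross-validated accuracy: (mean pct, sd pct, folds).

    ``fit_fn(train: Dataset) -> model`` fits one candidate; folds partition
    the rows and are deterministic per seed.
    """
    y = dataset.labels.astype(str)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > y.value_counts().min():
        raise ValueError("k exceeds the smallest class size")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(dataset.features, y):
        train = Dataset(dataset.features.iloc[train_idx], y.iloc[train_idx], dataset.class_names)
        test = Dataset(dataset.features.iloc[test_idx], y.iloc[test_idx], dataset.class_names)
        model = fit_fn(train)
        accs.append(evaluate(model, test).overall_accuracy_pct)
    arr = np.array(accs)
    return float(arr.mean()), float(arr.std(ddof=1)) if k > 1 else 0.0, accs


def random_projection_2d(features: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Project the feature matrix to 2D with a Gaussian random projection.

    The projection matrix has i.i.d. N(0, 1/2) entries (1/sqrt(d) scaling
    with d=2), approximately preserving pairwise distances.  Deterministic
    per seed; duplicate rows map to identical coordinates.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("random projection requires at least two features")
    proj = GaussianRandomProjection(n_components=2, random_state=seed)
    return proj.fit_transform(X)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _check_schema(expected: tuple[str, ...], features: pd.DataFrame) -> None:
    if tuple(features.columns) != expected:
        raise ValueError(
            f"feature schema mismatch: model expects {list(expected)}, got {list(features.columns)}"
        )


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model to a JSON manifest.

    LDA stores its discriminant coefficients in full; the forest stores its
    configuration and seed — refitting on the same training data reproduces
    it bit-for-bit, which keeps artifacts small and text-only.
    """
    path = Path(path)
    if isinstance(model, LdaModel):
        manifest = {
            "model_kind": "lda",
            "class_names": list(model.class_names),
            "columns": list(model.columns),
            "priors": model.priors,
            "coef": model.estimator.coef_.tolist(),
            "intercept": model.estimator.intercept_.tolist(),
            "classes_": model.estimator.classes_.tolist(),
            "training_accuracy_pct": model.training_accuracy_pct,
        }
    elif isinstance(model, ForestModel):
        manifest = {
            "model_kind": "random_forest",
            "class_names": list(model.class_names),
            "columns": list(model.columns),
            "n_trees": model.n_trees,
            "mtry": model.mtry,
            "seed": model.seed,
            "training_accuracy_pct": model.training_accuracy_pct,
            "oob_error_pct": model.oob_error_pct,
            "note": "refit deterministically from seed + training data to reproduce",
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model)!r}")
    path.write_text(json.dumps(manifest, indent=2))


def load_lda(path: str | Path) -> LdaModel:
    """Rebuild a serialized LDA from its JSON manifest (decision-rule exact)."""
    manifest = json.loads(Path(path).read_text())
    if manifest["model_kind"] != "lda":
        raise ValueError("manifest is not an LDA model")
    est = LinearDiscriminantAnalysis()
    est.coef_ = np.array(manifest["coef"])
    est.intercept_ = np.array(manifest["intercept"])
    est.classes_ = np.array(manifest["classes_"])
    return LdaModel(
        estimator=est,
        class_names=tuple(manifest["class_names"]),
        columns=tuple(manifest["columns"]),
        priors=manifest["priors"],
        training_accuracy_pct=manifest["training_accuracy_pct"],
    )
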