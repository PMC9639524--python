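"""Orchestration of the sex/ancestry classification experiment matrix.

Five tasks are supported, each defined by how rows are labelled (and, for
the sex-specific ancestry tasks, filtered):

* ``sex_only`` — two classes (M/F), the three populations pooled;
* ``ancestry_only`` — three classes (Egyptian/Greek/Indian), sexes pooled;
* ``sex_ancestry_6way`` — six group-by-sex classes simultaneously;
* ``ancestry_in_males`` / ``ancestry_in_females`` — three ancestry classes
  on the recorded-sex subset, gauging the value of prior sex knowledge.

Each experiment derives one of the six feature sets, splits 70/30
(stratified), fits one of the two classifiers, and evaluates train and test
partitions; forest runs add the OOB error and both variable-importance
measures.  ``run_matrix`` sweeps tasks x feature sets x classifiers over
replicate seeds and emits tidy accuracy grids (a single 70/30 split has
high variance at these cell sizes, so replicate means with SDs are the
default reporting unit; single-split mode is just one seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, geometry
from .classify import Dataset, EvalReport, ImportanceReport, SplitSpec

__all__ = [
    "TASKS",
    "ExperimentSpec",
    "ExperimentResult",
    "build_labels",
    "run_experiment",
    "run_matrix",
    "plot_accuracy_grid",
]

TASKS = (
    "sex_only",
    "ancestry_only",
    "sex_ancestry_6way",
    "ancestry_in_males",
    "ancestry_in_females",
)


@dataclass(frozen=True)
class ExperimentSpec:
    """One classification task x feature set x classifier configuration."""

    task: str
    feature_set: str = "linear"
    classifier: str = "lda"
    split: SplitSpec = SplitSpec()
    priors: str = "equal"
    n_trees: int = 500
    mtry: int | None = None
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.feature_set not in geometry.FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.classifier not in ("lda", "random_forest"):
            raise ValueError("classifier must be 'lda' or 'random_forest'")


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    train_report: EvalReport
    test_report: EvalReport
    oob_error_pct: float | None = None
    importance: ImportanceReport | None = None
    n_train: int = 0
    n_test: int = 0


def build_labels(table: pd.DataFrame, task: str) -> pd.DataFrame:
    """Filter rows and attach the task's class label column ``label``.

    Row order is preserved; for the sex-specific ancestry tasks the
    opposite-sex rows are dropped before labelling.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    out = table.copy()
    if task == "sex_only":
        out["label"] = out["sex"].astype(str)
    elif task == "ancestry_only":
        out["label"] = out["group"].astype(str)
    elif task == "sex_ancestry_6way":
        out["label"] = out["group"].astype(str) + "_" + out["sex"].astype(str)
    elif task == "ancestry_in_males":
        out = out[out["sex"].astype(str) == "M"].copy()
        out["label"] = out["group"].astype(str)
    else:  # ancestry_in_females
        out = out[out["sex"].astype(str) == "F"].copy()
        out["label"] = out["group"].astype(str)
    if out.empty or out["label"].nunique() < 2:
        raise ValueError(f"task {task!r} leaves fewer than two populated classes")
    return out


def _make_dataset(table: pd.DataFrame, feature_set: str) -> Dataset:
    features = geometry.derive_feature_table(table, set_name=feature_set)
    return Dataset(features, table["label"].reset_index(drop=True))


def _fit(spec: ExperimentSpec, train: Dataset):
    if spec.classifier == "lda":
        return classify.fit_lda(train, priors=spec.priors)
    return classify.fit_random_forest(
        train,
        n_trees=spec.n_trees,
        mtry=spec.mtry,
        seed=spec.split.seed,
        min_samples_leaf=spec.min_samples_leaf,
    )


def run_experiment(spec: ExperimentSpec, table: pd.DataFrame) -> ExperimentResult:
    """Derive features, split, fit, evaluate train and test; fully seeded.

    Forest runs also report the OOB error and the MDA/MDI importances
    computed on the training partition's OOB samples.
    """
    labelled = build_labels(table, spec.task).reset_index(drop=True)
    dataset = _make_dataset(labelled, spec.feature_set)
    train, test = classify.split(dataset, spec.split)
    model = _fit(spec, train)
    result = ExperimentResult(
        spec=spec,
        train_report=classify.evaluate(model, train),
        test_report=classify.evaluate(model, test),
        n_train=len(train),
        n_test=len(test),
    )
    if spec.classifier == "random_forest":
        result.oob_error_pct = model.oob_error_pct
        result.importance = classify.importance(model, seed=spec.split.seed)
    return result


def run_matrix(
    table: pd.DataFrame,
    tasks: Sequence[str] = TASKS,
    feature_sets: Sequence[str] = tuple(geometry.FEATURE_SETS),
    classifiers: Sequence[str] = ("lda", "random_forest"),
    seeds: Sequence[int] = tuple(range(25)),
    **spec_kwargs,
) -> tuple[list[ExperimentResult], pd.DataFrame]:
    """Sweep the experiment grid over replicate seeds.

    Returns all individual results plus a tidy grid with one row per
    (task, feature_set, classifier) carrying replicate mean and SD of the
    overall test accuracy and of each per-class test accuracy.
    """
    if len(seeds) < 1:
        raise ValueError("at least one seed is required")
    results: list[ExperimentResult] = []
    grid_rows = []
    for task in tasks:
        for feature_set in feature_sets:
            for classifier in classifiers:
                overall, per_class = [], []
                for seed in seeds:
                    spec = ExperimentSpec(
                        task=task, feature_set=feature_set, classifier=classifier,
                        split=SplitSpec(seed=seed), **spec_kwargs,
                    )
                    res = run_experiment(spec, table)
                    results.append(res)
                    overall.append(res.test_report.overall_accuracy_pct)
                    per_class.append(res.test_report.per_class_accuracy_pct)
                per_class_frame = pd.DataFrame(per_class)
                row = {
                    "task": task, "feature_set": feature_set, "classifier": classifier,
                    "n_seeds": len(seeds),
                    "test_overall_mean": float(np.mean(overall)),
                    "test_overall_sd": float(np.std(overall, ddof=1)) if len(seeds) > 1 else 0.0,
                }
                for cls in per_class_frame.columns:
                    row[f"test_{cls}_mean"] = float(per_class_frame[cls].mean())
                    row[f"test_{cls}_sd"] = (
                        float(per_class_frame[cls].std(ddof=1)) if len(seeds) > 1 else 0.0
                    )
                grid_rows.append(row)
    return results, pd.DataFrame(grid_rows)


def plot_accuracy_grid(grid: pd.DataFrame, task: str, out_path: str) -> None:
    """Cosmetic bar chart of a task's classifier x feature-set accuracies."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = grid[grid["task"] == task]
    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.35
    feature_sets = sub["feature_set"].unique()
    x = np.arange(len(feature_sets))
    for i, clf in enumerate(sub["classifier"].unique()):
        vals = [
            sub[(sub["feature_set"] == fs) & (sub["classifier"] == clf)]["test_overall_mean"].iloc[0]
            for fs in feature_sets
        ]
        ax.bar(x + i * width, vals, width, label=clf)
    ax.set_xticks(x + width / 2)
    ax.set_xticklabels(feature_sets, rotation=30)
    ax.set_ylabel("test accuracy (%)")
    ax.set_title(task)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
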