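"""Random-forest training, hyperparameter search and model/dataset selection.

The protocol mirrors a small-data regime: each balanced dataset is split
70/30 (stratified); a randomized hyperparameter search with stratified
five-fold cross-validation on the training part yields one candidate
configuration per dataset; every candidate is then retrained on every
dataset's 70% split (no further search) and scored on the 30% holdout,
producing an n x n evaluation grid from which the final model/dataset
combination is chosen by consistent performance (mean AUROC, then mean
accuracy, then mean F1).  The final forest always carries 500 trees so the
reported interaction probability is a mean over 500 tree votes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence, Union

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    ParameterSampler,
    StratifiedKFold,
    train_test_split,
)

from .evaluation import MetricBundle, metric_bundle
from .ground_truth import LabeledDataset
from .pair_features import FEATURE_COLUMNS

__all__ = [
    "DEFAULT_SPACE",
    "DESK_SCALE_SPACE",
    "FINAL_TREE_COUNT",
    "TrainedModel",
    "ModelSelectionResult",
    "dataset_frame",
    "split_70_30",
    "randomized_search",
    "train_final",
    "cross_dataset_grid",
    "select_final",
    "run_model_selection",
    "feature_importances",
    "save_model",
    "load_model",
    "load_space_yaml",
]

#: Trees in the final model: interaction probability is the mean vote of 500
#: individual decision trees.
FINAL_TREE_COUNT = 500

#: Randomized-search space.  Standard ranges around the parameters known to
#: matter for forest capacity (tree count, depth, feature subsampling, leaf
#: sizes); configurable via YAML.
DEFAULT_SPACE: dict[str, list] = {
    "n_estimators": list(range(100, 1001, 100)),
    "max_depth": [*range(2, 21), None],
    "max_features": ["sqrt", "log2", None],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
}

#: Reduced space for desk-scale runs (synthetic scenarios, examples, smoke
#: runs): small forests suffice to rank configurations on a 204-pair
#: dataset, and the final model is refit at 500 trees regardless.
DESK_SCALE_SPACE: dict[str, list] = {
    "n_estimators": [10, 25, 50],
    "max_depth": [2, 4, 6, 8, None],
    "max_features": ["sqrt", "log2", None],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
}

GRID_METRICS = ["accuracy", "precision", "recall", "f1", "auroc", "fdr"]


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to reproduce it."""

    estimator: RandomForestClassifier
    hyperparameters: dict[str, Any]
    dataset_name: str
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    seed: int = 0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean positive-class probability over the forest's trees."""
        pos = list(self.estimator.classes_).index(1)
        return self.estimator.predict_proba(X)[:, pos]


@dataclass
class ModelSelectionResult:
    final_model: TrainedModel
    selected_dataset: str
    candidates: dict[str, dict[str, Any]]
    grid: pd.DataFrame
    holdout_metrics: MetricBundle

    def mean_holdout_auroc(self) -> float:
        rows = self.grid[self.grid["candidate"] == self.selected_dataset]
        return float(rows["auroc"].mean())


def dataset_frame(dataset: LabeledDataset, feature_table: pd.DataFrame) -> pd.DataFrame:
    """Join a labeled dataset with its feature rows (inner, order-stable)."""
    labels = pd.DataFrame(dataset.pairs, columns=["pvog_a", "pvog_b", "label"])
    merged = labels.merge(feature_table, on=["pvog_a", "pvog_b"], how="inner")
    if len(merged) < len(labels):
        raise ValueError(
            f"dataset {dataset.name}: {len(labels) - len(merged)} pairs have "
            "no feature row"
        )
    return merged


def _xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return df[FEATURE_COLUMNS].to_numpy(dtype=float), df["label"].to_numpy(dtype=int)


def split_70_30(df: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 70/30 split; the holdout takes ceil(0.3 n) rows."""
    labels = df["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain both classes for a stratified split")
    train, holdout = train_test_split(
        df, test_size=0.3, stratify=labels, random_state=seed
    )
    return train, holdout


def randomized_search(
    train: pd.DataFrame,
    space: Mapping[str, Sequence] | None = None,
    n_iter: int = 500,
    cv_folds: int = 5,
    seed: int = 0,
) -> dict[str, Any]:
    """Sample configurations and rank them by mean CV AUROC.

    Returns the first-sampled configuration achieving the maximum mean
    AUROC over a stratified ``cv_folds``-fold split of the training data.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    space = dict(space or DEFAULT_SPACE)
    X, y = _xy(train)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    for _, test_idx in folds:
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("a CV fold contains a single class")
    best_score = -np.inf
    best_params: dict[str, Any] | None = None
    for params in ParameterSampler(space, n_iter=n_iter, random_state=seed):
        fold_scores = []
        for train_idx, test_idx in folds:
            clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
            clf.fit(X[train_idx], y[train_idx])
            pos = list(clf.classes_).index(1)
            proba = clf.predict_proba(X[test_idx])[:, pos]
            fold_scores.append(roc_auc_score(y[test_idx], proba))
        score = float(np.mean(fold_scores))
        if score > best_score:
            best_score = score
            best_params = dict(params)
    assert best_params is not None
    return best_params


def train_final(
    train: pd.DataFrame,
    hyperparameters: Mapping[str, Any],
    seed: int = 0,
    dataset_name: str = "",
    n_trees: int | None = FINAL_TREE_COUNT,
) -> TrainedModel:
    """Fit a forest with the given configuration on the training split.

    ``n_trees`` overrides the searched ``n_estimators`` (default 500) so
    that reported probabilities are always a mean over 500 tree votes; pass
    ``None`` to keep the searched value.
    """
    params = dict(hyperparameters)
    if n_trees is not None:
        params["n_estimators"] = n_trees
    X, y = _xy(train)
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    clf.fit(X, y)
    return TrainedModel(
        estimator=clf,
        hyperparameters=params,
        dataset_name=dataset_name,
        feature_columns=list(FEATURE_COLUMNS),
        seed=seed,
    )


def _evaluate(model: TrainedModel, holdout: pd.DataFrame) -> MetricBundle:
    X, y = _xy(holdout)
    proba = model.predict_proba(X)
    return metric_bundle(y, (proba > 0.5).astype(int), scores=proba)


def cross_dataset_grid(
    candidates: Mapping[str, Mapping[str, Any]],
    datasets: Mapping[str, pd.DataFrame],
    seed: int = 0,
) -> pd.DataFrame:
    """Retrain every candidate configuration on every dataset and score it.

    Each dataset gets one fixed 70/30 split shared by all candidates; the
    cell where a candidate meets its own optimization dataset uses a fresh
    split (flagged in the ``fresh_split`` column) so the score is not read
    off data the search already saw.
    """
    ds_names = sorted(datasets)
    splits = {
        name: split_70_30(datasets[name], seed + 101 * i)
        for i, name in enumerate(ds_names)
    }
    rows = []
    for cand_name in sorted(candidates):
        for i, ds_name in enumerate(ds_names):
            fresh = cand_name == ds_name
            if fresh:
                train, holdout = split_70_30(datasets[ds_name], seed + 101 * i + 7919)
            else:
                train, holdout = splits[ds_name]
            model = train_final(
                train,
                candidates[cand_name],
                seed=seed,
                dataset_name=ds_name,
                n_trees=None,  # grid cells keep the searched tree count
            )
            bundle = _evaluate(model, holdout)
            rows.append(
                {
                    "candidate": cand_name,
                    "dataset": ds_name,
                    "fresh_split": fresh,
                    **bundle.as_dict(),
                }
            )
    return pd.DataFrame(rows)


def select_final(grid: pd.DataFrame) -> str:
    """Pick the candidate with the best mean performance across datasets.

    Ranking: mean AUROC, ties by mean accuracy, then mean F1, then the
    lexicographically first candidate name.
    """
    means = (
        grid.groupby("candidate")[["auroc", "accuracy", "f1"]]
        .mean()
        .reset_index()
        .sort_values(
            by=["auroc", "accuracy", "f1", "candidate"],
            ascending=[False, False, False, True],
            kind="mergesort",
        )
    )
    return str(means.iloc[0]["candidate"])


def run_model_selection(
    datasets: Mapping[str, pd.DataFrame],
    seed: int = 0,
    n_iter: int = 500,
    cv_folds: int = 5,
    space: Mapping[str, Sequence] | None = None,
) -> ModelSelectionResult:
    """Full protocol: per-dataset search, cross-dataset grid, final model."""
    ds_names = sorted(datasets)
    candidates: dict[str, dict[str, Any]] = {}
    for i, name in enumerate(ds_names):
        train, _ = split_70_30(datasets[name], seed + 101 * i)
        candidates[name] = randomized_search(
            train, space=space, n_iter=n_iter, cv_folds=cv_folds, seed=seed + 101 * i
        )
    grid = cross_dataset_grid(candidates, datasets, seed=seed)
    winner = select_final(grid)
    w_idx = ds_names.index(winner)
    train, holdout = split_70_30(datasets[winner], seed + 101 * w_idx)
    final_model = train_final(
        train, candidates[winner], seed=seed, dataset_name=winner
    )
    return ModelSelectionResult(
        final_model=final_model,
        selected_dataset=winner,
        candidates=candidates,
        grid=grid,
        holdout_metrics=_evaluate(final_model, holdout),
    )


def feature_importances(model: TrainedModel) -> list[tuple[str, float]]:
    """Gini importances, normalized to sum 1, descending."""
    raw = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = raw.sum()
    if total > 0:
        raw = raw / total
    ranked = sorted(zip(model.feature_columns, raw), key=lambda kv: -kv[1])
    return [(name, float(v)) for name, v in ranked]


def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Serialize the forest plus a JSON sidecar with its metadata."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "hyperparameters": {
            k: v for k, v in model.hyperparameters.items()
        },
        "dataset_name": model.dataset_name,
        "feature_columns": model.feature_columns,
        "seed": model.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: Union[str, Path]) -> TrainedModel:
    path = Path(path)
    estimator = joblib.load(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return TrainedModel(
        estimator=estimator,
        hyperparameters=sidecar["hyperparameters"],
        dataset_name=sidecar["dataset_name"],
        feature_columns=sidecar["feature_columns"],
        seed=sidecar["seed"],
    )


def load_space_yaml(path: Union[str, Path]) -> dict[str, list]:
    """Load a search-space YAML ({parameter: [choices, ...]})."""
    with open(path) as fh:
        space = yaml.safe_load(fh)
    if not isinstance(space, dict) or not space:
        raise ValueError(f"{path}: search space must be a non-empty mapping")
    return {k: list(v) for k, v in space.items()}
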