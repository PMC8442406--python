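"""End-to-end orchestration helpers shared by the CLI, examples and tests.

These functions wire the stages together in the canonical order:
occurrence index -> positive set -> sampled negative sets -> feature table
-> labeled dataset frames -> model selection -> target-set prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classifier import ModelSelectionResult, dataset_frame, run_model_selection
from .ground_truth import (
    LabeledDataset,
    assemble_datasets,
    build_positive_set,
    sample_negative_sets,
)
from .hmm_hits import OccurrenceIndex
from .pair_features import build_feature_table
from .synthetic_data import TrainingScenario

__all__ = ["PreparedDatasets", "prepare_datasets", "select_model"]


@dataclass
class PreparedDatasets:
    index: OccurrenceIndex
    positives: list[tuple[str, str]]
    datasets: list[LabeledDataset]
    feature_table: pd.DataFrame
    dataset_frames: dict[str, pd.DataFrame]


def prepare_datasets(
    training: TrainingScenario,
    n_sets: int = 10,
    size: int | None = None,
    seed: int = 0,
) -> PreparedDatasets:
    """Build the balanced labeled datasets and their feature rows.

    ``size`` defaults to the number of positives, giving the balanced
    design (e.g. 102 positives + 102 negatives per dataset).
    """
    scenario = training.scenario
    index = scenario.index()
    positives = build_positive_set(
        training.protein_pairs, training.protein_to_pvog, index
    )
    size = size or len(positives)
    negative_sets = sample_negative_sets(
        training.candidate_pairs, positives, n_sets=n_sets, size=size, seed=seed
    )
    datasets = assemble_datasets(positives, negative_sets)
    all_pairs = {(a, b) for ds in datasets for a, b, _ in ds.pairs}
    feature_table = build_feature_table(index, scenario.ani, scenario.aai, all_pairs)
    frames = {ds.name: dataset_frame(ds, feature_table) for ds in datasets}
    return PreparedDatasets(
        index=index,
        positives=positives,
        datasets=datasets,
        feature_table=feature_table,
        dataset_frames=frames,
    )


def select_model(
    prepared: PreparedDatasets | Mapping[str, pd.DataFrame],
    seed: int = 0,
    n_iter: int = 25,
    cv_folds: int = 5,
    space: Mapping[str, Sequence] | None = None,
) -> ModelSelectionResult:
    """Run the search / cross-dataset evaluation / selection protocol."""
    frames = (
        prepared.dataset_frames
        if isinstance(prepared, PreparedDatasets)
        else dict(prepared)
    )
    return run_model_selection(
        frames, seed=seed, n_iter=n_iter, cv_folds=cv_folds, space=space
    )
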