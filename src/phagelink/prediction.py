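"""Applying the final model: scoring pairs, summarizing, transferring labels.

Each target pair gets a probability (mean over the forest's 500 tree
votes).  A pair is called interacting when its probability exceeds 0.5;
calls at or above the high-confidence cutoff (0.65 by default) are flagged
separately.  Positive predictions are stratified by annotation status
(both / one / neither group annotated) and, for guilt-by-association,
every unannotated group is linked to its annotated partners above the
cutoff, providing a preliminary functional hint and an overall linkage
rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .annotation_text import PvogAnnotation
from .classifier import TrainedModel
from .pair_features import FEATURE_COLUMNS

__all__ = [
    "HIGH_CONFIDENCE_CUTOFF",
    "POSITIVE_CUTOFF",
    "PredictionRecord",
    "predict_pairs",
    "annotation_status",
    "add_annotation_status",
    "transfer_annotations",
    "summarize",
    "top_annotated_pairs",
]

logger = logging.getLogger(__name__)

POSITIVE_CUTOFF = 0.5  # strictly greater -> predicted interacting
HIGH_CONFIDENCE_CUTOFF = 0.65  # at or above -> high confidence

BOTH_ANNOTATED = "both_annotated"
ONE_ANNOTATED = "one_annotated"
NONE_ANNOTATED = "none_annotated"


@dataclass(frozen=True)
class PredictionRecord:
    pvog_a: str
    pvog_b: str
    probability: float
    label: int
    confidence: str
    annotation_status: str | None = None


def predict_pairs(
    model: TrainedModel,
    feature_table: pd.DataFrame,
    high_cutoff: float = HIGH_CONFIDENCE_CUTOFF,
) -> pd.DataFrame:
    """Score every feature row with the trained forest.

    Columns of the feature table must match the model's recorded feature
    order; a mismatch raises with the missing/extra names.  The returned
    frame has pvog_a, pvog_b, probability, label (1 iff probability > 0.5)
    and confidence ('high' iff probability >= ``high_cutoff``).
    """
    expected = set(model.feature_columns)
    present = set(feature_table.columns) - {"pvog_a", "pvog_b", "label"}
    if expected - present or present - expected:
        raise ValueError(
            f"feature columns mismatch: missing {sorted(expected - present)}, "
            f"extra {sorted(present - expected)}"
        )
    X = feature_table[model.feature_columns].to_numpy(dtype=float)
    proba = model.predict_proba(X)
    out = feature_table[["pvog_a", "pvog_b"]].copy()
    out["probability"] = proba
    out["label"] = (proba > POSITIVE_CUTOFF).astype(int)
    out["confidence"] = ["high" if p >= high_cutoff else "low" for p in proba]
    return out


def _is_annotated(
    pvog: str, annotations: Mapping[str, PvogAnnotation | bool]
) -> bool:
    entry = annotations.get(pvog)
    if entry is None:
        logger.debug("group %s absent from annotation table; treated unknown", pvog)
        return False
    if isinstance(entry, PvogAnnotation):
        return entry.is_annotated
    return bool(entry)


def annotation_status(
    pvog_a: str, pvog_b: str, annotations: Mapping[str, PvogAnnotation | bool]
) -> str:
    """Three-way category by how many of the two groups are annotated."""
    n = int(_is_annotated(pvog_a, annotations)) + int(_is_annotated(pvog_b, annotations))
    return (NONE_ANNOTATED, ONE_ANNOTATED, BOTH_ANNOTATED)[n]


def add_annotation_status(
    predictions: pd.DataFrame, annotations: Mapping[str, PvogAnnotation | bool]
) -> pd.DataFrame:
    out = predictions.copy()
    out["annotation_status"] = [
        annotation_status(a, b, annotations)
        for a, b in zip(out["pvog_a"], out["pvog_b"])
    ]
    return out


def transfer_annotations(
    predictions: pd.DataFrame,
    annotations: Mapping[str, PvogAnnotation],
    cutoff: float = HIGH_CONFIDENCE_CUTOFF,
) -> tuple[dict[str, list[tuple[str, str, float]]], list[str]]:
    """Guilt-by-association transfer to unannotated groups.

    For each unannotated group, collect the annotated partners predicted at
    probability >= ``cutoff``, ranked by descending probability (pair
    lexicographic on ties).  Returns (linked, unlinked): the ranked-partner
    map and the list of unannotated groups with no qualifying partner.
    """
    if not (0.5 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0.5, 1], got {cutoff}")
    unknown = sorted(
        pvog for pvog, ann in annotations.items() if not ann.is_annotated
    )
    linked: dict[str, list[tuple[str, str, float]]] = {}
    strong = predictions[predictions["probability"] >= cutoff]
    for row in strong.itertuples(index=False):
        for target, partner in ((row.pvog_a, row.pvog_b), (row.pvog_b, row.pvog_a)):
            ann_t = annotations.get(target)
            ann_p = annotations.get(partner)
            if ann_t is None or ann_t.is_annotated:
                continue
            if ann_p is None or not ann_p.is_annotated:
                continue
            linked.setdefault(target, []).append(
                (partner, ann_p.processed_annotation, float(row.probability))
            )
    for partners in linked.values():
        partners.sort(key=lambda t: (-t[2], t[0]))
    unlinked = [p for p in unknown if p not in linked]
    return linked, unlinked


def _pct(count: int, denominator: int) -> float:
    """Percentage rounded to one decimal; 0.0 for an empty denominator."""
    return round(100.0 * count / denominator, 1) if denominator else 0.0


def summarize(
    predictions: pd.DataFrame,
    annotations: Mapping[str, PvogAnnotation] | None = None,
    high_cutoff: float = HIGH_CONFIDENCE_CUTOFF,
) -> dict:
    """Counts and percentages of the prediction run.

    Reports predicted positives among all pairs, high-confidence calls
    among positives (both at-or-above and strictly-above the cutoff, since
    either convention may be wanted), the three annotation-status
    categories among positives, unique groups covered and the
    guilt-by-association linkage rate of unannotated groups.
    """
    total = len(predictions)
    positives = predictions[predictions["label"] == 1]
    n_pos = len(positives)
    high_ge = int((positives["probability"] >= high_cutoff).sum())
    high_gt = int((positives["probability"] > high_cutoff).sum())
    summary = {
        "total_pairs": total,
        "predicted_positive": n_pos,
        "predicted_positive_pct": _pct(n_pos, total),
        "high_confidence_ge_cutoff": high_ge,
        "high_confidence_ge_cutoff_pct": _pct(high_ge, n_pos),
        "high_confidence_gt_cutoff": high_gt,
        "high_confidence_gt_cutoff_pct": _pct(high_gt, n_pos),
        "high_confidence_cutoff": high_cutoff,
        "unique_pvogs": int(
            pd.concat([predictions["pvog_a"], predictions["pvog_b"]]).nunique()
        ),
    }
    if annotations is not None:
        with_status = add_annotation_status(positives, annotations)
        for category in (BOTH_ANNOTATED, ONE_ANNOTATED, NONE_ANNOTATED):
            count = int((with_status["annotation_status"] == category).sum())
            summary[category] = count
            summary[f"{category}_pct"] = _pct(count, n_pos)
        linked, unlinked = transfer_annotations(
            predictions, annotations, cutoff=high_cutoff
        )
        n_unknown = len(linked) + len(unlinked)
        summary["unknown_pvogs"] = n_unknown
        summary["unknown_pvogs_linked"] = len(linked)
        summary["unknown_pvogs_linked_pct"] = _pct(len(linked), n_unknown)
    return summary


def top_annotated_pairs(
    predictions: pd.DataFrame,
    annotations: Mapping[str, PvogAnnotation],
    n: int = 15,
) -> pd.DataFrame:
    """Top predicted interactions where both groups are annotated.

    Sorted by probability descending, ties broken by the lexicographic
    pair; columns pvog_a, pvog_b, probability, annotation_a, annotation_b.
    """
    with_status = add_annotation_status(predictions, annotations)
    both = with_status[with_status["annotation_status"] == BOTH_ANNOTATED].copy()
    both = both.sort_values(
        by=["probability", "pvog_a", "pvog_b"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(n)
    both["annotation_a"] = [
        annotations[p].processed_annotation for p in both["pvog_a"]
    ]
    both["annotation_b"] = [
        annotations[p].processed_annotation for p in both["pvog_b"]
    ]
    return both[
        ["pvog_a", "pvog_b", "probability", "annotation_a", "annotation_b"]
    ].reset_index(drop=True)
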