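"""Construction of labeled datasets and the all-pairs target set.

The positive class comes from a curated list of physically interacting
protein pairs; each protein is mapped to its best-matching orthologous
group, and the resulting group pairs are kept only if the two groups
co-occur on at least one genome (interactions are only meaningful between
proteins that can meet).  Because true non-interaction is unknowable, ten
negative sets of the same size are sampled from co-occurring candidate
pairs not present in the positive set, each combined with the same
positives into balanced datasets N1..N10.  The target set for prediction is
every remaining unordered group pair that co-occurs on at least one genome.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .hmm_hits import OccurrenceIndex

__all__ = [
    "LabeledDataset",
    "TargetSet",
    "build_positive_set",
    "sample_negative_sets",
    "assemble_datasets",
    "ground_truth_exclusion",
    "build_target_set",
]

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def normalize_pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class LabeledDataset:
    """A balanced set of labeled group pairs (one of N1..N10)."""

    name: str
    pairs: tuple[tuple[str, str, int], ...]

    @property
    def positives(self) -> list[Pair]:
        return [(a, b) for a, b, y in self.pairs if y == 1]

    @property
    def negatives(self) -> list[Pair]:
        return [(a, b) for a, b, y in self.pairs if y == 0]


@dataclass(frozen=True)
class TargetSet:
    pairs: tuple[Pair, ...]


def _co_occurs(index: OccurrenceIndex, pair: Pair) -> bool:
    return bool(index.co_occurring_genomes(*pair))


def build_positive_set(
    protein_pairs: Iterable[tuple[str, str]],
    protein_to_pvog: Mapping[str, str | tuple],
    index: OccurrenceIndex,
) -> list[Pair]:
    """Map interacting protein pairs to co-occurring group pairs.

    ``protein_to_pvog`` may map to a bare group ID or to a
    ``(pvog, bitscore, evalue)`` best-hit tuple.  Protein pairs with an
    unmapped member are dropped with a log message; pairs whose proteins
    map to the same group (self-pairs) and pairs whose groups never share a
    genome are excluded; duplicates collapse.
    """
    mapping = {
        prot: (val[0] if isinstance(val, tuple) else val)
        for prot, val in protein_to_pvog.items()
    }
    kept: set[Pair] = set()
    n_unmapped = n_self = n_disjoint = 0
    for p1, p2 in protein_pairs:
        if p1 not in mapping or p2 not in mapping:
            n_unmapped += 1
            continue
        a, b = mapping[p1], mapping[p2]
        if a == b:
            n_self += 1
            continue
        pair = normalize_pair(a, b)
        if not _co_occurs(index, pair):
            n_disjoint += 1
            continue
        kept.add(pair)
    if n_unmapped or n_self or n_disjoint:
        logger.info(
            "positive set: dropped %d unmapped, %d self-mapped, %d never "
            "co-occurring protein pairs",
            n_unmapped,
            n_self,
            n_disjoint,
        )
    return sorted(kept)


def sample_negative_sets(
    candidate_pairs: Iterable[Pair],
    positive_set: Iterable[Pair],
    n_sets: int,
    size: int,
    seed: int,
) -> list[list[Pair]]:
    """Sample ``n_sets`` negative sets of ``size`` pairs each.

    Sampling is without replacement within each set, from the sorted
    candidates minus the positives, with per-set seeds derived as
    ``seed + i`` so the draw is reproducible and order-invariant in the
    candidate input.  Distinct sets may overlap each other.
    """
    positives = {normalize_pair(*p) for p in positive_set}
    pool = sorted({normalize_pair(*p) for p in candidate_pairs} - positives)
    if len(pool) < size:
        raise ValueError(
            f"need {size} negative candidates, only {len(pool)} available "
            f"after excluding {len(positives)} positives"
        )
    sets: list[list[Pair]] = []
    for i in range(n_sets):
        rng = np.random.default_rng(seed + i)
        idx = rng.choice(len(pool), size=size, replace=False)
        sets.append(sorted(pool[j] for j in idx))
    return sets


def assemble_datasets(
    positive_set: Sequence[Pair], negative_sets: Sequence[Sequence[Pair]]
) -> list[LabeledDataset]:
    """Combine the shared positives with each negative set into N1..N10."""
    datasets = []
    positives = tuple((a, b, 1) for a, b in sorted(positive_set))
    for i, negatives in enumerate(negative_sets, start=1):
        rows = positives + tuple((a, b, 0) for a, b in sorted(negatives))
        datasets.append(LabeledDataset(name=f"N{i}", pairs=rows))
    return datasets


def ground_truth_exclusion(
    positive_set: Sequence[Pair],
    negative_sets: Sequence[Sequence[Pair]],
    selected: int | None = None,
    exclude_all: bool = False,
) -> set[Pair]:
    """The pairs to exclude from the target set at prediction time.

    By default the exclusion is the positives plus the negatives of the
    selected training dataset (``selected`` is its 0-based index) — the
    "positives + one negative set" reading of the ground truth.  With
    ``exclude_all=True`` the union of every sampled negative set is
    excluded instead, the stricter reading.
    """
    excluded = {normalize_pair(*p) for p in positive_set}
    if exclude_all:
        for negatives in negative_sets:
            excluded.update(normalize_pair(*p) for p in negatives)
    elif selected is not None:
        excluded.update(normalize_pair(*p) for p in negative_sets[selected])
    return excluded


def build_target_set(
    all_pvogs: Iterable[str],
    ground_truth_pairs: Iterable[Pair],
    index: OccurrenceIndex,
) -> TargetSet:
    """All unordered group pairs minus ground truth, co-occurring somewhere."""
    excluded = {normalize_pair(*p) for p in ground_truth_pairs}
    pairs = tuple(
        pair
        for pair in itertools.combinations(sorted(set(all_pvogs)), 2)
        if pair not in excluded and _co_occurs(index, pair)
    )
    return TargetSet(pairs=pairs)
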