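"""Free-text annotation processing and weighted-cosine annotation similarity.

Each orthologous group carries the free-text annotations of its member
proteins, which vary in number and syntax.  Cleaning replaces the phrase
"hypothetical protein" with "unknown" and deletes the filler tokens
"protein" and "putative"; the majority cleaned string becomes the group's
single processed annotation.  For similarity, a corpus is built from the
informative terms of all groups, each term weighted by its inverse
document frequency (1 - fraction of groups carrying it) so rarer terms
count more, and pairs of groups are compared by the weighted cosine
distance between their term-count vectors.  An inverse relationship
between that distance and the predicted interaction probability is the
annotation-based sanity check of the whole pipeline.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import math

import pandas as pd
from scipy import stats

from .evaluation import UNDEFINED, Undefined

__all__ = [
    "STOPLIST",
    "PvogAnnotation",
    "TermCorpus",
    "clean_annotation",
    "process_annotations",
    "tokenize",
    "build_annotation",
    "read_annotation_tsv",
    "build_corpus",
    "weighted_cosine_distance",
    "distance_vs_probability",
]

#: Terms excluded from the similarity corpus: misspelled variants of
#: "hypothetical", placeholder words and glue words that carry no
#: functional information.
STOPLIST = (
    "hypothetical",
    "hypotheical",
    "hypothetical-acquired",
    "hypotthetical",
    "hypothethical",
    "hyphothetical",
    "hypothetical-protein",
    "hypho",
    "predicted",
    "protein",
    "unknown",
    "putative",
    "phage",
    "bacteriophage",
    "no",
    "annotation",
    "provided",
    "gene",
    "and",
    "in",
    "conserved",
    "#",
    "&",
)

_PUNCT_RE = re.compile(r"[^\w\s#&-]")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class PvogAnnotation:
    """Processed annotation state of one group."""

    pvog_id: str
    raw_terms: tuple[str, ...]
    processed_annotation: str
    term_vector: dict[str, int]
    informative_term_count: int

    @property
    def is_annotated(self) -> bool:
        return self.processed_annotation not in ("", "unknown")


@dataclass(frozen=True)
class TermCorpus:
    """Corpus terms with inverse-document-frequency weights in [0, 1)."""

    terms: frozenset[str]
    weight: dict[str, float]


def clean_annotation(text: str) -> str:
    """Lowercase, map 'hypothetical protein' to 'unknown', drop fillers."""
    s = text.lower()
    s = s.replace("hypothetical protein", "unknown")
    tokens = [t for t in s.split() if t not in ("protein", "putative")]
    return _WS_RE.sub(" ", " ".join(tokens)).strip()


def process_annotations(raw: Sequence[str]) -> str:
    """Majority vote over cleaned strings; ties go to the lexicographic min."""
    if not raw:
        raise ValueError("need at least one raw annotation string")
    counts = Counter(clean_annotation(s) for s in raw)
    top = max(counts.values())
    return min(s for s, c in counts.items() if c == top)


def tokenize(text: str) -> list[str]:
    """Lowercase tokens split on whitespace; punctuation except '-' stripped.

    '#' and '&' survive as standalone tokens so the stoplist can catch
    them.
    """
    cleaned = _PUNCT_RE.sub(" ", text.lower())
    return [t for t in cleaned.split() if t and t != "-"]


def build_annotation(
    pvog_id: str, raw: Sequence[str], stoplist: Iterable[str] = STOPLIST
) -> PvogAnnotation:
    """Assemble the per-group annotation state from member-protein strings.

    The term vector counts informative tokens over all cleaned member
    annotations; the informative term count is the number of distinct such
    terms.
    """
    stop = set(stoplist)
    processed = process_annotations(raw)
    vector: Counter[str] = Counter()
    for s in raw:
        for token in tokenize(clean_annotation(s)):
            if token not in stop:
                vector[token] += 1
    return PvogAnnotation(
        pvog_id=pvog_id,
        raw_terms=tuple(raw),
        processed_annotation=processed,
        term_vector=dict(vector),
        informative_term_count=len(vector),
    )


def read_annotation_tsv(
    path: Union[str, Path], stoplist: Iterable[str] = STOPLIST
) -> dict[str, PvogAnnotation]:
    """Read a two-column TSV (pvog_id, annotation), one member protein per row."""
    per_pvog: dict[str, list[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty annotation table")
        for row in reader:
            if len(row) < 2:
                continue
            per_pvog.setdefault(row[0], []).append(row[1])
    return {
        pvog: build_annotation(pvog, raws, stoplist)
        for pvog, raws in sorted(per_pvog.items())
    }


def build_corpus(
    annotations: Iterable[PvogAnnotation], stoplist: Iterable[str] = STOPLIST
) -> TermCorpus:
    """Document-frequency-weighted corpus over groups with informative terms.

    frequency(t) = (# groups whose term set contains t) /
                   (# groups with >= 1 informative term);
    weight(t) = 1 - frequency(t).
    """
    stop = set(stoplist)
    doc_freq: Counter[str] = Counter()
    n_docs = 0
    for ann in annotations:
        terms = {t for t in ann.term_vector if t not in stop}
        if not terms:
            continue
        n_docs += 1
        doc_freq.update(terms)
    if n_docs == 0:
        raise ValueError("empty corpus: no group has an informative term")
    weight = {t: 1.0 - c / n_docs for t, c in doc_freq.items()}
    return TermCorpus(terms=frozenset(weight), weight=weight)


def weighted_cosine_distance(
    vec_a: Mapping[str, float],
    vec_b: Mapping[str, float],
    corpus: TermCorpus,
) -> float | Undefined:
    """1 - weighted cosine similarity of two term-count vectors.

    The weight enters once in the inner product and once in each norm:
    d = 1 - sum(w a b) / (sqrt(sum(w a^2)) * sqrt(sum(w b^2))), summed over
    the corpus terms.  Returns UNDEFINED when either vector has zero
    weighted norm; otherwise clipped to [0, 1] (exact for non-negative
    count vectors).
    """
    num = norm_a = norm_b = 0.0
    for term, w in corpus.weight.items():
        a = vec_a.get(term, 0.0)
        b = vec_b.get(term, 0.0)
        num += w * a * b
        norm_a += w * a * a
        norm_b += w * b * b
    if norm_a == 0.0 or norm_b == 0.0:
        return UNDEFINED
    d = 1.0 - num / (math.sqrt(norm_a) * math.sqrt(norm_b))
    return min(1.0, max(0.0, d))


def distance_vs_probability(
    predictions: pd.DataFrame,
    annotations: Mapping[str, PvogAnnotation],
    min_terms: int = 3,
    corpus: TermCorpus | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation of interaction probability vs annotation distance.

    Restricted to pairs where both groups individually have at least
    ``min_terms`` informative terms; returns (r, two-sided p, n_pairs).
    """
    if min_terms < 1:
        raise ValueError("min_terms must be >= 1")
    if corpus is None:
        corpus = build_corpus(annotations.values())
    probs: list[float] = []
    dists: list[float] = []
    for row in predictions.itertuples(index=False):
        ann_a = annotations.get(row.pvog_a)
        ann_b = annotations.get(row.pvog_b)
        if ann_a is None or ann_b is None:
            continue
        if (
            ann_a.informative_term_count < min_terms
            or ann_b.informative_term_count < min_terms
        ):
            continue
        d = weighted_cosine_distance(ann_a.term_vector, ann_b.term_vector, corpus)
        if isinstance(d, Undefined):
            continue
        probs.append(float(row.probability))
        dists.append(d)
    if len(probs) < 3:
        raise ValueError(
            f"only {len(probs)} eligible pairs with >= {min_terms} informative "
            "terms each; need >= 3"
        )
    r, p = stats.pearsonr(probs, dists)
    return float(r), float(p), len(probs)
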