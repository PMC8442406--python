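"""The seven genomic-context features for a pair of protein groups.

For an unordered group pair (a, b) the feature vector comprises:

* ``co_occurrence`` — Jaccard similarity of the genome sets carrying the
  two groups, |G_a ∩ G_b| / |G_a ∪ G_b|;
* ``avg_distance`` — the minimum nucleotide gap between the two groups'
  hit envelopes, averaged across all common genomes;
* ``f_co`` / ``f_conv`` / ``f_div`` — fractions of common genomes whose
  closest hit pair is co-oriented, convergent (opposite strands, 3' ends
  facing) or divergent (opposite strands, 5' ends facing);
* ``mean_ani`` / ``mean_aai`` — mean nucleotide / amino-acid identity over
  all unordered pairs of distinct common genomes.

All features except co-occurrence are computed only on genomes where both
groups have a significant hit.  When a pair co-occurs on a single genome
there are no genome pairs to average identity over; 100.0 is imputed (a
genome is fully identical to itself), and likewise when every matrix entry
for the common genomes is missing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genome_similarity import IdentityMatrix
from .hmm_hits import HmmHit, OccurrenceIndex

__all__ = [
    "PairFeatures",
    "FEATURE_COLUMNS",
    "co_occurrence",
    "min_pair_distance",
    "classify_orientation",
    "pair_features",
    "build_feature_table",
]

logger = logging.getLogger(__name__)

#: Feature column order used everywhere a matrix is assembled.
FEATURE_COLUMNS = [
    "co_occurrence",
    "avg_distance",
    "f_co",
    "f_conv",
    "f_div",
    "mean_ani",
    "mean_aai",
]

CO = "co"
CONVERGENT = "convergent"
DIVERGENT = "divergent"


@dataclass(frozen=True)
class PairFeatures:
    pvog_a: str
    pvog_b: str
    co_occurrence: float
    avg_distance: float
    f_co: float
    f_conv: float
    f_div: float
    mean_ani: float
    mean_aai: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "pvog_a": self.pvog_a,
            "pvog_b": self.pvog_b,
            "co_occurrence": self.co_occurrence,
            "avg_distance": self.avg_distance,
            "f_co": self.f_co,
            "f_conv": self.f_conv,
            "f_div": self.f_div,
            "mean_ani": self.mean_ani,
            "mean_aai": self.mean_aai,
        }


def co_occurrence(index: OccurrenceIndex, a: str, b: str) -> float:
    """Jaccard similarity of the genome sets of groups ``a`` and ``b``."""
    ga = index.genomes_of.get(a)
    gb = index.genomes_of.get(b)
    if not ga or not gb:
        missing = a if not ga else b
        raise ValueError(f"group {missing!r} has no genome occurrences")
    return len(ga & gb) / len(ga | gb)


def gap(h1: HmmHit, h2: HmmHit) -> int:
    """Nucleotide gap between two hit envelopes; 0 for overlap/adjacency."""
    s1, e1 = h1.interval.start, h1.interval.end
    s2, e2 = h2.interval.start, h2.interval.end
    return max(0, max(s1, s2) - min(e1, e2) - 1)


def min_pair_distance(
    hits_a: Sequence[HmmHit], hits_b: Sequence[HmmHit]
) -> tuple[int, HmmHit, HmmHit]:
    """Closest cross pair of hits on one genome.

    Ties broken by the smallest (start_a, start_b).
    """
    if not hits_a or not hits_b:
        raise ValueError("both hit lists must be non-empty")
    best: tuple[int, int, int] | None = None
    best_pair: tuple[HmmHit, HmmHit] | None = None
    for ha in hits_a:
        for hb in hits_b:
            key = (gap(ha, hb), ha.interval.start, hb.interval.start)
            if best is None or key < best:
                best = key
                best_pair = (ha, hb)
    assert best is not None and best_pair is not None
    return best[0], best_pair[0], best_pair[1]


def classify_orientation(hit_a: HmmHit, hit_b: HmmHit) -> str:
    """Orientation relationship of two hits on one genome.

    Same strand -> co-oriented.  On opposite strands the upstream hit (the
    one with the smaller start) decides: upstream on '+' means the 3' ends
    face inward (convergent); upstream on '-' means the 5' ends face inward
    (divergent).
    """
    sa, sb = hit_a.interval.strand, hit_b.interval.strand
    if sa == sb:
        return CO
    upstream = min(hit_a, hit_b, key=lambda h: (h.interval.start, h.interval.end))
    return CONVERGENT if upstream.interval.strand == "+" else DIVERGENT


def _mean_identity(matrix: IdentityMatrix | None, genomes: Sequence[str]) -> float:
    pairs = list(itertools.combinations(sorted(genomes), 2))
    if not pairs:
        return 100.0  # single common genome: identical to itself
    if matrix is None:
        logger.warning("no identity matrix supplied; imputing 100.0")
        return 100.0
    values = [v for a, b in pairs if (v := matrix.get(a, b)) is not None]
    if not values:
        logger.warning(
            "all identity values missing for %d genome pairs; imputing 100.0",
            len(pairs),
        )
        return 100.0
    return float(sum(values) / len(values))


def pair_features(
    index: OccurrenceIndex,
    ani: IdentityMatrix | None,
    aai: IdentityMatrix | None,
    a: str,
    b: str,
) -> PairFeatures:
    """Compute the seven-feature vector for the unordered pair (a, b)."""
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    pvog_a, pvog_b = sorted((a, b))
    jaccard = co_occurrence(index, pvog_a, pvog_b)
    if jaccard == 0.0:
        raise ValueError(f"pair ({pvog_a}, {pvog_b}) shares no genome")
    common = sorted(index.co_occurring_genomes(pvog_a, pvog_b))
    distances: list[int] = []
    orient_counts = {CO: 0, CONVERGENT: 0, DIVERGENT: 0}
    for genome in common:
        dist, ha, hb = min_pair_distance(
            index.hits_on[(genome, pvog_a)], index.hits_on[(genome, pvog_b)]
        )
        distances.append(dist)
        orient_counts[classify_orientation(ha, hb)] += 1
    n = len(common)
    return PairFeatures(
        pvog_a=pvog_a,
        pvog_b=pvog_b,
        co_occurrence=jaccard,
        avg_distance=float(sum(distances) / n),
        f_co=orient_counts[CO] / n,
        f_conv=orient_counts[CONVERGENT] / n,
        f_div=orient_counts[DIVERGENT] / n,
        mean_ani=_mean_identity(ani, common),
        mean_aai=_mean_identity(aai, common),
    )


def build_feature_table(
    index: OccurrenceIndex,
    ani: IdentityMatrix | None,
    aai: IdentityMatrix | None,
    pairs: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Feature rows for every co-occurring pair, in deterministic order.

    Pairs that never share a genome (or reference unknown groups) are
    dropped; the dropped count is logged.
    """
    rows: list[dict[str, float | str]] = []
    dropped = 0
    normalized = sorted({tuple(sorted(p)) for p in pairs})
    for a, b in normalized:
        try:
            rows.append(pair_features(index, ani, aai, a, b).as_dict())
        except ValueError:
            dropped += 1
    if dropped:
        logger.info("dropped %d pairs without a shared genome", dropped)
    return pd.DataFrame(rows, columns=["pvog_a", "pvog_b", *FEATURE_COLUMNS])
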