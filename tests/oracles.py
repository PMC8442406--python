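"""Independent brute-force reference implementations used by the tests.

These deliberately re-derive the quantities from first principles
(exhaustive enumeration over hits and score pairs) rather than calling the
package's own code paths.
"""

from __future__ import annotations

import itertools


def jaccard_from_hits(hits, a, b):
    genomes_a = {h.genome_id for h in hits if h.pvog_id == a}
    genomes_b = {h.genome_id for h in hits if h.pvog_id == b}
    return len(genomes_a & genomes_b) / len(genomes_a | genomes_b)


def _interval_gap(iv1, iv2):
    if iv1.start > iv2.end:
        return iv1.start - iv2.end - 1
    if iv2.start > iv1.end:
        return iv2.start - iv1.end - 1
    return 0


def _orientation(iv_a, iv_b):
    if iv_a.strand == iv_b.strand:
        return "co"
    first = iv_a if (iv_a.start, iv_a.end) <= (iv_b.start, iv_b.end) else iv_b
    return "convergent" if first.strand == "+" else "divergent"


def features_by_enumeration(hits, a, b):
    """Average minimum distance and orientation fractions for pair (a, b),
    enumerated exhaustively over all cross hit pairs per shared genome."""
    genomes_a = {h.genome_id for h in hits if h.pvog_id == a}
    genomes_b = {h.genome_id for h in hits if h.pvog_id == b}
    common = sorted(genomes_a & genomes_b)
    distances = []
    orient = {"co": 0, "convergent": 0, "divergent": 0}
    for g in common:
        on_a = [h for h in hits if h.pvog_id == a and h.genome_id == g]
        on_b = [h for h in hits if h.pvog_id == b and h.genome_id == g]
        candidates = [
            (_interval_gap(ha.interval, hb.interval),
             ha.interval.start, hb.interval.start, ha, hb)
            for ha, hb in itertools.product(on_a, on_b)
        ]
        dist, _, _, ha, hb = min(candidates)
        distances.append(dist)
        orient[_orientation(ha.interval, hb.interval)] += 1
    n = len(common)
    return {
        "avg_distance": sum(distances) / n,
        "f_co": orient["co"] / n,
        "f_conv": orient["convergent"] / n,
        "f_div": orient["divergent"] / n,
    }


def concordance_auroc(labels, scores):
    """AUROC as the Mann-Whitney concordance probability with tie credit."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def weighted_cosine_by_enumeration(vec_a, vec_b, weights):
    terms = sorted(weights)
    num = sum(weights[t] * vec_a.get(t, 0) * vec_b.get(t, 0) for t in terms)
    na = sum(weights[t] * vec_a.get(t, 0) ** 2 for t in terms) ** 0.5
    nb = sum(weights[t] * vec_b.get(t, 0) ** 2 for t in terms) ** 0.5
    return 1.0 - num / (na * nb)


def random_hit_set(rng, n_genomes=5, n_pvogs=4, max_hits_per_pvog=6):
    """A random small occurrence instance for oracle comparisons."""
    from conftest import make_hit

    genome_len = 2000
    hits = []
    for p in range(n_pvogs):
        pvog = f"P{p}"
        n_hits = rng.integers(1, max_hits_per_pvog + 1)
        for _ in range(n_hits):
            g = f"g{rng.integers(n_genomes)}"
            start = int(rng.integers(1, genome_len - 100))
            end = start + int(rng.integers(10, 100))
            strand = "+" if rng.random() < 0.5 else "-"
            hits.append(make_hit(pvog, g, start, end, strand))
    return hits
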