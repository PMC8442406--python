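"""Desk-scale synthetic inputs with the genomic signals the pipeline assumes.

The generator emulates the structure that makes guilt-by-association work
in phage genomes: functionally linked gene pairs sit in conserved cassettes
— they co-occur on many of the same genomes, lie a short exponential gap
apart, are usually co-oriented, and favour a core of mutually similar
genomes — while unlinked genes are scattered independently.  Genomes are
drawn from a star phylogeny around a random ancestor, so nucleotide and
amino-acid identity matrices follow directly from the per-genome
substitution rates.  Hits are emitted directly as placed-hit tables in the
exact shapes the downstream modules read; no HMM search is involved.

A ``signal=False`` scenario places every group by the independent
background process and labels a random sample of co-occurring pairs as
"interacting", which makes positives and negatives exchangeable — the null
control for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .genome_similarity import IdentityMatrix
from .hmm_hits import HmmHit, OccurrenceIndex, build_occurrence_index, write_hits_tsv
from .sequence_io import GenomeRecord, NtInterval

__all__ = [
    "SyntheticScenario",
    "ScenarioData",
    "TrainingScenario",
    "generate_scenario",
    "generate_training_scenario",
]

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Functional vocabularies; an annotated interacting pair shares one theme.
THEMES = (
    ("tail", "fiber", "spike", "baseplate", "adhesin"),
    ("capsid", "head", "scaffolding", "portal", "decoration"),
    ("terminase", "packaging", "subunit", "motor", "atpase"),
    ("holin", "lysin", "endolysin", "spanin", "lysis"),
    ("polymerase", "helicase", "primase", "ligase", "replication"),
    ("integrase", "recombinase", "excisionase", "repressor", "lysogeny"),
    ("methyltransferase", "nuclease", "exonuclease", "glycosylase", "repair"),
    ("tape", "measure", "minor", "major", "structural"),
)
GENERIC_TERMS = ("domain", "family", "type", "early", "late", "accessory")


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults are the study conditions used throughout the test suite: 30
    genomes of 100 kb, 102 interacting pairs (the size of the curated
    positive set the pipeline is built around) plus 60 background groups,
    cassette gaps of mean 150 nt, 90% co-orientation, and a core/diverse
    split of the genome set that plants the genome-similarity signal.
    """

    n_genomes: int = 30
    genome_length: int = 100_000
    n_interacting_pairs: int = 102
    n_background_pvogs: int = 60
    gene_length_range: tuple[int, int] = (300, 900)
    cassette_distance_mean: float = 150.0
    co_orientation_prob: float = 0.9
    co_occurrence_prob_interacting: float = 0.35
    co_occurrence_prob_background: float = 0.12
    stray_cassette_prob: float = 0.05  # cassette appearing on a non-core genome
    solo_prob: float = 0.03  # cassette member appearing alone on a genome
    core_fraction: float = 0.5
    core_mutation_range: tuple[float, float] = (0.0, 0.04)
    diverse_mutation_range: tuple[float, float] = (0.08, 0.30)
    annotated_prob: float = 0.3
    proteins_per_pvog: tuple[int, int] = (3, 8)
    signal: bool = True

    def __post_init__(self) -> None:
        n_pvogs = 2 * self.n_interacting_pairs + self.n_background_pvogs
        for p in (
            self.co_orientation_prob,
            self.co_occurrence_prob_interacting,
            self.co_occurrence_prob_background,
            self.solo_prob,
            self.annotated_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_interacting_pairs > n_pvogs * (n_pvogs - 1) // 2:
            raise ValueError("more interacting pairs requested than group pairs exist")


@dataclass
class ScenarioData:
    """All cross-consistent outputs of one generated scenario."""

    params: SyntheticScenario
    seed: int
    genomes: list[GenomeRecord]
    hits: list[HmmHit]
    interacting_pairs: list[tuple[str, str]]
    annotations: dict[str, list[str]]
    ani: IdentityMatrix
    aai: IdentityMatrix
    pvogs: list[str] = field(default_factory=list)

    def index(self) -> OccurrenceIndex:
        return build_occurrence_index(
            self.hits, {g.genome_id: g.length for g in self.genomes}
        )

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Emit every output in the on-disk formats the modules read."""
        from .genome_similarity import write_identity_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genomes": outdir / "genomes.fna",
            "hits": outdir / "hits.tsv",
            "ani": outdir / "ani.tsv",
            "aai": outdir / "aai.tsv",
            "annotations": outdir / "annotations.tsv",
            "interacting_pairs": outdir / "interacting_pairs.tsv",
        }
        with open(paths["genomes"], "w") as fh:
            for g in self.genomes:
                fh.write(f">{g.genome_id}\n{g.sequence}\n")
        write_hits_tsv(self.hits, paths["hits"])
        write_identity_tsv(self.ani, paths["ani"])
        write_identity_tsv(self.aai, paths["aai"])
        with open(paths["annotations"], "w") as fh:
            fh.write("pvog_id\tannotation\n")
            for pvog in sorted(self.annotations):
                for text in self.annotations[pvog]:
                    fh.write(f"{pvog}\t{text}\n")
        with open(paths["interacting_pairs"], "w") as fh:
            fh.write("pvog_a\tpvog_b\n")
            for a, b in self.interacting_pairs:
                fh.write(f"{a}\t{b}\n")
        return paths


@dataclass
class TrainingScenario:
    """A scenario plus the protein-level shapes the ground-truth stage reads."""

    scenario: ScenarioData
    protein_pairs: list[tuple[str, str]]
    protein_to_pvog: dict[str, tuple[str, float, float]]
    positive_pairs: list[tuple[str, str]]
    candidate_pairs: list[tuple[str, str]]


def _mutate(ancestor: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    genome = ancestor.copy()
    n_mut = rng.binomial(len(genome), rate)
    if n_mut:
        sites = rng.choice(len(genome), size=n_mut, replace=False)
        # shift each mutated site to a different base
        shifts = rng.integers(1, 4, size=n_mut)
        lookup = {c: i for i, c in enumerate(NUCLEOTIDES)}
        idx = np.array([lookup[c] for c in genome[sites]])
        genome[sites] = NUCLEOTIDES[(idx + shifts) % 4]
    return genome


def _identity_matrices(
    genome_arrays: dict[str, np.ndarray]
) -> tuple[IdentityMatrix, IdentityMatrix]:
    """Exact ANI from pairwise Hamming identity; AAI as its protein-space
    counterpart (substitutions are partly synonymous, so amino-acid identity
    degrades at ~60% of the nucleotide substitution load)."""
    ani = IdentityMatrix(kind="ANI")
    aai = IdentityMatrix(kind="AAI")
    names = sorted(genome_arrays)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            mismatch = float(np.mean(genome_arrays[a] != genome_arrays[b]))
            ani.set(a, b, 100.0 * (1.0 - mismatch))
            aai.set(a, b, max(0.0, 100.0 * (1.0 - 0.6 * mismatch)))
    return ani, aai


def _place_items(
    items: list[list[tuple[str, int, str, int]]],
    genome_id: str,
    genome_length: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, str]]:
    """Lay out gene items left to right with random spacers; no overlap.

    Each item is a list of (pvog, length, strand, gap_after) genes.  Raises
    when the genome cannot hold the requested content.
    """
    total = sum(length + gap for item in items for _, length, _, gap in item)
    if total > genome_length:
        raise ValueError(
            f"infeasible packing on {genome_id}: {total} nt of genes requested "
            f"for a {genome_length} nt genome"
        )
    order = rng.permutation(len(items))
    spacers = rng.multinomial(
        genome_length - total, np.full(len(items) + 1, 1.0 / (len(items) + 1))
    )
    placed: list[tuple[str, int, int, str]] = []
    pos = 0
    for slot, item_idx in enumerate(order):
        pos += int(spacers[slot])
        for pvog, length, strand, gap_after in items[item_idx]:
            start = pos + 1
            end = pos + length
            placed.append((pvog, start, end, strand))
            pos = end + gap_after
    return placed


def _cassette_item(
    pair: tuple[str, str],
    params: SyntheticScenario,
    rng: np.random.Generator,
) -> list[tuple[str, int, str, int]]:
    lo, hi = params.gene_length_range
    len_a, len_b = int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))
    gap = int(rng.exponential(params.cassette_distance_mean))
    a, b = pair if rng.random() < 0.5 else (pair[1], pair[0])
    if rng.random() < params.co_orientation_prob:
        strand = "+" if rng.random() < 0.5 else "-"
        strands = (strand, strand)
    elif rng.random() < 0.5:
        strands = ("+", "-")  # convergent: 3' ends face inward
    else:
        strands = ("-", "+")  # divergent: 5' ends face inward
    return [(a, len_a, strands[0], gap), (b, len_b, strands[1], 0)]


def _solo_item(
    pvog: str, params: SyntheticScenario, rng: np.random.Generator
) -> list[tuple[str, int, str, int]]:
    lo, hi = params.gene_length_range
    return [
        (pvog, int(rng.integers(lo, hi + 1)), "+" if rng.random() < 0.5 else "-", 0)
    ]


def _emit_hits(
    placed: list[tuple[str, int, int, str]],
    genome_id: str,
    genome_length: int,
    rng: np.random.Generator,
) -> list[HmmHit]:
    hits = []
    for pvog, start, end, strand in placed:
        if strand == "+":
            frame = (start - 1) % 3 + 1
        else:
            frame = (genome_length - end) % 3 + 4
        hits.append(
            HmmHit(
                pvog_id=pvog,
                genome_id=genome_id,
                interval=NtInterval(start, end, strand),
                bitscore=float(np.round(rng.uniform(60, 300), 1)),
                evalue=float(10.0 ** -rng.uniform(6, 60)),
                frame=frame,
            )
        )
    return hits


def _make_annotations(
    interacting: list[tuple[str, str]],
    background: list[str],
    params: SyntheticScenario,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    annotations: dict[str, list[str]] = {}
    theme_of: dict[str, tuple[str, ...]] = {}
    annotated: set[str] = set()
    for a, b in interacting:
        theme = THEMES[int(rng.integers(len(THEMES)))]
        for pvog in (a, b):
            if rng.random() < params.annotated_prob:
                annotated.add(pvog)
                theme_of.setdefault(pvog, theme)  # shared within the pair
    for pvog in background:
        if rng.random() < params.annotated_prob:
            annotated.add(pvog)
            theme_of[pvog] = THEMES[int(rng.integers(len(THEMES)))]
    all_pvogs = sorted({p for pair in interacting for p in pair} | set(background))
    lo, hi = params.proteins_per_pvog
    for pvog in all_pvogs:
        n_prot = int(rng.integers(lo, hi + 1))
        if pvog not in annotated:
            annotations[pvog] = ["hypothetical protein"] * n_prot
            continue
        theme = theme_of[pvog]
        base_terms = list(rng.choice(theme, size=3, replace=False))
        base = " ".join(base_terms) + " protein"
        texts = []
        for _ in range(n_prot):
            u = rng.random()
            if u < 0.7:
                texts.append(base)
            elif u < 0.85:
                extra = GENERIC_TERMS[int(rng.integers(len(GENERIC_TERMS)))]
                texts.append(" ".join(base_terms[:2]) + f" {extra} protein")
            else:
                texts.append("hypothetical protein")
        annotations[pvog] = texts
    return annotations


def generate_scenario(params: SyntheticScenario, seed: int) -> ScenarioData:
    """Generate genomes, placed hits, labels, annotations and identity
    matrices, all mutually consistent and reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    n_pvogs = 2 * params.n_interacting_pairs + params.n_background_pvogs
    width = max(4, len(str(n_pvogs)))
    pvogs = [f"VOG{i:0{width}d}" for i in range(1, n_pvogs + 1)]
    cassette_pvogs = pvogs[: 2 * params.n_interacting_pairs]
    background_pvogs = pvogs[2 * params.n_interacting_pairs :]
    interacting = [
        (cassette_pvogs[2 * i], cassette_pvogs[2 * i + 1])
        for i in range(params.n_interacting_pairs)
    ]

    genome_ids = [f"g{i:03d}" for i in range(params.n_genomes)]
    n_core = max(1, round(params.core_fraction * params.n_genomes))
    core = set(genome_ids[:n_core])
    rates = {
        gid: float(
            rng.uniform(*params.core_mutation_range)
            if gid in core
            else rng.uniform(*params.diverse_mutation_range)
        )
        for gid in genome_ids
    }

    ancestor = rng.choice(NUCLEOTIDES, size=params.genome_length)
    genome_arrays = {gid: _mutate(ancestor, rates[gid], rng) for gid in genome_ids}
    genomes = [
        GenomeRecord(gid, genome_arrays[gid].tobytes().decode(), params.genome_length)
        for gid in genome_ids
    ]

    items_per_genome: dict[str, list[list[tuple[str, int, str, int]]]] = {
        gid: [] for gid in genome_ids
    }
    if params.signal:
        for pair in interacting:
            chosen = [
                gid
                for gid in genome_ids
                if rng.random()
                < (
                    params.co_occurrence_prob_interacting
                    if gid in core
                    else params.stray_cassette_prob
                )
            ]
            if not chosen:
                chosen = [sorted(core)[int(rng.integers(len(core)))]]
            for gid in chosen:
                items_per_genome[gid].append(_cassette_item(pair, params, rng))
            for pvog in pair:
                for gid in genome_ids:
                    if rng.random() < params.solo_prob:
                        items_per_genome[gid].append(_solo_item(pvog, params, rng))
        scatter = background_pvogs
    else:
        scatter = pvogs  # no cassettes at all: every group is background
    for pvog in scatter:
        placed_any = False
        for gid in genome_ids:
            if rng.random() < params.co_occurrence_prob_background:
                items_per_genome[gid].append(_solo_item(pvog, params, rng))
                placed_any = True
        if not placed_any:
            gid = genome_ids[int(rng.integers(len(genome_ids)))]
            items_per_genome[gid].append(_solo_item(pvog, params, rng))

    hits: list[HmmHit] = []
    for gid in genome_ids:
        placed = _place_items(
            items_per_genome[gid], gid, params.genome_length, rng
        )
        hits.extend(_emit_hits(placed, gid, params.genome_length, rng))

    labeled_pairs = sorted(tuple(sorted(p)) for p in interacting)
    if not params.signal:
        labeled_pairs = []  # assigned downstream by sampling co-occurring pairs
    ani, aai = _identity_matrices(genome_arrays)
    annotations = _make_annotations(interacting, background_pvogs, params, rng)
    return ScenarioData(
        params=params,
        seed=seed,
        genomes=genomes,
        hits=hits,
        interacting_pairs=labeled_pairs,
        annotations=annotations,
        ani=ani,
        aai=aai,
        pvogs=pvogs,
    )


def _co_occurring_pairs(index: OccurrenceIndex) -> list[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    per_genome: dict[str, set[str]] = {}
    for pvog, genomes in index.genomes_of.items():
        for gid in genomes:
            per_genome.setdefault(gid, set()).add(pvog)
    for members in per_genome.values():
        ordered = sorted(members)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pairs.add((a, b))
    return sorted(pairs)


def generate_training_scenario(
    params: SyntheticScenario | None = None,
    seed: int = 0,
    n_known_positives: int | None = None,
) -> TrainingScenario:
    """A scenario plus the interacting-protein list and best-hit mapping.

    Positive pairs are expressed as protein pairs whose members map to the
    interacting groups, in the shapes the ground-truth builder consumes;
    candidate negatives are all other co-occurring group pairs.
    ``n_known_positives`` limits how many planted interacting pairs are
    exposed in the curated positive list; the rest stay latent in the
    candidate/target space, emulating the usual situation where most true
    interactions are absent from the curated set.  In a ``signal=False``
    scenario the "positives" are instead a random sample of co-occurring
    pairs, making the two classes exchangeable.
    """
    params = params or SyntheticScenario()
    scenario = generate_scenario(params, seed)
    rng = np.random.default_rng(seed + 1)
    index = scenario.index()
    co_pairs = _co_occurring_pairs(index)
    if params.signal:
        positives = list(scenario.interacting_pairs)
        if n_known_positives is not None and n_known_positives < len(positives):
            idx = rng.choice(len(positives), size=n_known_positives, replace=False)
            positives = sorted(positives[i] for i in sorted(idx))
    else:
        if len(co_pairs) < params.n_interacting_pairs:
            raise ValueError(
                f"null scenario yields only {len(co_pairs)} co-occurring pairs; "
                f"{params.n_interacting_pairs} positives requested"
            )
        idx = rng.choice(len(co_pairs), size=params.n_interacting_pairs, replace=False)
        positives = sorted(co_pairs[i] for i in idx)
        scenario.interacting_pairs = positives
    protein_pairs: list[tuple[str, str]] = []
    protein_to_pvog: dict[str, tuple[str, float, float]] = {}
    for i, (a, b) in enumerate(positives, start=1):
        pa, pb = f"prot{i:04d}a", f"prot{i:04d}b"
        protein_pairs.append((pa, pb))
        protein_to_pvog[pa] = (a, float(np.round(rng.uniform(60, 300), 1)), 1e-20)
        protein_to_pvog[pb] = (b, float(np.round(rng.uniform(60, 300), 1)), 1e-20)
    positives_set = set(positives)
    candidates = [p for p in co_pairs if p not in positives_set]
    return TrainingScenario(
        scenario=scenario,
        protein_pairs=protein_pairs,
        protein_to_pvog=protein_to_pvog,
        positive_pairs=positives,
        candidate_pairs=candidates,
    )
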