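"""Parsing of hmmsearch domain tables and construction of the occurrence index.

The pipeline searches every protein-family profile HMM against six-frame
translated genomes; the resulting per-domain table (``--domtblout``) is the
raw evidence.  Rows are filtered on the full-sequence E-value, envelope
coordinates are mapped from amino-acid frame space back to genome
nucleotide space, and the resulting :class:`HmmHit` records are organised
into an :class:`OccurrenceIndex` — per-group genome sets plus per-genome hit
lists — which is the substrate for every genomic-context feature.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .sequence_io import GenomeRecord, NtInterval, aa_to_nt_interval

__all__ = [
    "DomtblRow",
    "HmmHit",
    "OccurrenceIndex",
    "parse_domtblout",
    "filter_and_place",
    "build_occurrence_index",
    "best_hit_per_target",
    "write_hits_tsv",
    "read_hits_tsv",
]

#: Default significance cutoff on the full-sequence E-value.
DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class DomtblRow:
    """One domain row of an hmmsearch ``--domtblout`` table."""

    target_name: str
    query_name: str
    evalue: float  # full-sequence E-value
    bitscore: float  # full-sequence bit score
    env_from: int  # envelope start, aa space, 1-based
    env_to: int
    genome_id: str | None = None
    frame: int | None = None


@dataclass(frozen=True)
class HmmHit:
    """A significant profile match placed on a genome in nucleotide space."""

    pvog_id: str
    genome_id: str
    interval: NtInterval
    bitscore: float
    evalue: float
    frame: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.pvog_id}/{self.genome_id}")


@dataclass
class OccurrenceIndex:
    """Per-group genome sets and per-(genome, group) hit lists."""

    genomes_of: dict[str, set[str]] = field(default_factory=dict)
    hits_on: dict[tuple[str, str], list[HmmHit]] = field(default_factory=dict)
    genome_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def pvogs(self) -> list[str]:
        return sorted(self.genomes_of)

    def co_occurring_genomes(self, a: str, b: str) -> set[str]:
        return self.genomes_of.get(a, set()) & self.genomes_of.get(b, set())


def _split_frame_suffix(target_name: str) -> tuple[str, int]:
    genome_id, sep, tail = target_name.rpartition("_frame")
    if not sep or not tail.isdigit() or not (1 <= int(tail) <= 6):
        raise ValueError(
            f"target name {target_name!r} lacks a '_frame<1-6>' suffix"
        )
    return genome_id, int(tail)


def parse_domtblout(
    path: Union[str, Path], require_frame: bool = True
) -> list[DomtblRow]:
    """Parse an HMMER3 per-domain table into :class:`DomtblRow` records.

    With ``require_frame=True`` (the genome-search case) target names must
    end in ``_frame<k>`` and the genome ID and frame are split out; with
    ``require_frame=False`` (the protein-search case used for best-hit
    mapping) target names are kept verbatim.
    """
    rows: list[DomtblRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 22 whitespace-delimited "
                    f"columns, found {len(fields)}"
                )
            try:
                evalue = float(fields[6])
                bitscore = float(fields[7])
                env_from = int(fields[19])
                env_to = int(fields[20])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}")
            genome_id = frame = None
            if require_frame:
                try:
                    genome_id, frame = _split_frame_suffix(fields[0])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}")
            rows.append(
                DomtblRow(
                    target_name=fields[0],
                    query_name=fields[3],
                    evalue=evalue,
                    bitscore=bitscore,
                    env_from=env_from,
                    env_to=env_to,
                    genome_id=genome_id,
                    frame=frame,
                )
            )
    return rows


def filter_and_place(
    rows: Iterable[DomtblRow],
    genomes: Mapping[str, Union[GenomeRecord, int]],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[HmmHit]:
    """Keep significant rows and map their envelopes to genome coordinates.

    ``genomes`` maps genome ID to either a :class:`GenomeRecord` or a plain
    length in nucleotides.  Envelope (not alignment) coordinates are used.
    """
    lengths = {
        gid: (g.length if isinstance(g, GenomeRecord) else int(g))
        for gid, g in genomes.items()
    }
    hits: list[HmmHit] = []
    for row in rows:
        if row.evalue > evalue_max:
            continue
        if row.genome_id is None or row.frame is None:
            raise ValueError(
                f"row for target {row.target_name!r} has no genome/frame; "
                "parse with require_frame=True"
            )
        if row.genome_id not in lengths:
            raise KeyError(f"genome {row.genome_id!r} not supplied")
        interval = aa_to_nt_interval(
            row.env_from, row.env_to, row.frame, lengths[row.genome_id]
        )
        hits.append(
            HmmHit(
                pvog_id=row.query_name,
                genome_id=row.genome_id,
                interval=interval,
                bitscore=row.bitscore,
                evalue=row.evalue,
                frame=row.frame,
            )
        )
    return hits


def build_occurrence_index(
    hits: Iterable[HmmHit],
    genome_lengths: Mapping[str, int] | None = None,
) -> OccurrenceIndex:
    """Index hits by group and by (genome, group).

    If ``genome_lengths`` is omitted, a lower bound (the largest hit end per
    genome) is recorded instead.
    """
    index = OccurrenceIndex()
    for hit in hits:
        index.genomes_of.setdefault(hit.pvog_id, set()).add(hit.genome_id)
        index.hits_on.setdefault((hit.genome_id, hit.pvog_id), []).append(hit)
        if genome_lengths is None:
            prev = index.genome_lengths.get(hit.genome_id, 0)
            index.genome_lengths[hit.genome_id] = max(prev, hit.interval.end)
    if genome_lengths is not None:
        for hit in index.hits_on:
            if hit[0] not in genome_lengths:
                raise KeyError(f"genome {hit[0]!r} missing from genome_lengths")
        index.genome_lengths = dict(genome_lengths)
    return index


def best_hit_per_target(
    rows: Iterable[DomtblRow],
) -> dict[str, tuple[str, float, float]]:
    """For each target protein, the best-scoring profile.

    Best = highest bit score; ties broken by smaller E-value, then by
    lexicographically smaller profile ID.  Input rows come from searching
    profiles against a protein FASTA (no frame suffix).
    """
    best: dict[str, tuple[float, float, str]] = {}
    for row in rows:
        key = (-row.bitscore, row.evalue, row.query_name)
        if row.target_name not in best or key < best[row.target_name]:
            best[row.target_name] = key
    return {
        target: (qname, -neg_bits, evalue)
        for target, (neg_bits, evalue, qname) in best.items()
    }


HIT_TSV_COLUMNS = [
    "pvog_id",
    "genome_id",
    "start",
    "end",
    "strand",
    "frame",
    "bitscore",
    "evalue",
]


def write_hits_tsv(hits: Sequence[HmmHit], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HIT_TSV_COLUMNS)
        for h in hits:
            writer.writerow(
                [
                    h.pvog_id,
                    h.genome_id,
                    h.interval.start,
                    h.interval.end,
                    h.interval.strand,
                    h.frame,
                    f"{h.bitscore:.1f}",
                    f"{h.evalue:.3g}",
                ]
            )


def read_hits_tsv(path: Union[str, Path]) -> list[HmmHit]:
    hits: list[HmmHit] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            hits.append(
                HmmHit(
                    pvog_id=row["pvog_id"],
                    genome_id=row["genome_id"],
                    interval=NtInterval(
                        int(row["start"]), int(row["end"]), row["strand"]
                    ),
                    bitscore=float(row["bitscore"]),
                    evalue=float(row["evalue"]),
                    frame=int(row["frame"]),
                )
            )
    return hits
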