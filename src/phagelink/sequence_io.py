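"""Genome FASTA input, six-frame translation and coordinate mapping.

Profile-HMM searches for viral protein families are run against six-frame
translations of whole phage genomes rather than predicted ORFs, so hits are
reported in amino-acid coordinates of a frame translation.  Everything
downstream (distances, orientations) lives in nucleotide space, so this
module owns the frame bookkeeping: forward frames 1-3 translate the plus
strand at offsets 0-2, frames 4-6 translate the reverse complement at
offsets 0-2, and ``aa_to_nt_interval`` maps an amino-acid envelope back to a
1-based inclusive nucleotide interval with strand.

Translation uses the bacterial/archaeal genetic code (table 11).  Stop
codons are translated and then rendered as ``X`` (the behaviour of EMBOSS
``transeq -clean``): profiles may legitimately match across them because the
search ran on raw frame translations, not ORFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from Bio import BiopythonWarning
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeRecord",
    "FrameTranslation",
    "NtInterval",
    "read_fasta",
    "six_frame_translate",
    "aa_to_nt_interval",
    "write_frame_fasta",
]

#: IUPAC nucleotide one-letter codes accepted on input.
IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")

TRANSLATION_TABLE = 11
STOP_SENTINEL = "X"


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide genome sequence with a unique identifier."""

    genome_id: str
    sequence: str
    length: int

    def __post_init__(self) -> None:
        if self.length != len(self.sequence) or self.length == 0:
            raise ValueError(
                f"genome {self.genome_id!r}: length {self.length} does not match "
                f"non-empty sequence of {len(self.sequence)} nt"
            )


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six frame translations of a genome."""

    genome_id: str
    frame: int
    aa_sequence: str


@dataclass(frozen=True, order=True)
class NtInterval:
    """A 1-based inclusive nucleotide interval with strand ('+' or '-')."""

    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def read_fasta(path: Union[str, Path]) -> list[GenomeRecord]:
    """Read nucleotide FASTA into :class:`GenomeRecord` objects.

    IDs are the first whitespace-delimited header token; sequences are
    uppercased.  Raises ``ValueError`` on an empty file or a duplicate ID.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, str(rec.seq).upper(), len(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _validate_nt(sequence: str, genome_id: str) -> None:
    bad = set(sequence) - IUPAC_NT
    if bad:
        raise ValueError(
            f"genome {genome_id!r} contains non-IUPAC nucleotide characters: "
            f"{sorted(bad)}"
        )


def six_frame_translate(genome: GenomeRecord) -> list[FrameTranslation]:
    """Translate a genome in all six frames with genetic code table 11.

    Stop codons become 'X'; ambiguous codons (e.g. containing N) translate
    to 'X' as well.  Frame k in 1..3 reads the forward strand from offset
    k-1; frame k in 4..6 reads the reverse complement from offset k-4.
    """
    seq = genome.sequence.upper()
    _validate_nt(seq, genome.genome_id)
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    out: list[FrameTranslation] = []
    for frame in range(1, 7):
        strand_seq = fwd if frame <= 3 else rev
        offset = (frame - 1) if frame <= 3 else (frame - 4)
        sub = strand_seq[offset : offset + 3 * ((len(strand_seq) - offset) // 3)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BiopythonWarning)
            aa = str(sub.translate(table=TRANSLATION_TABLE))
        out.append(
            FrameTranslation(genome.genome_id, frame, aa.replace("*", STOP_SENTINEL))
        )
    return out


def aa_to_nt_interval(
    aa_start: int, aa_end: int, frame: int, genome_length: int
) -> NtInterval:
    """Map an amino-acid interval on a frame translation to genome space.

    Coordinates are 1-based inclusive on both sides.  For reverse frames the
    interval is first located on the reverse complement and then mirrored
    onto the forward coordinate system, yielding strand '-'.
    """
    if not (1 <= aa_start <= aa_end):
        raise ValueError(f"invalid aa interval [{aa_start}, {aa_end}]")
    if frame not in range(1, 7):
        raise ValueError(f"frame must be in 1..6, got {frame}")
    if frame <= 3:
        offset = frame - 1
        start = offset + 3 * (aa_start - 1) + 1
        end = offset + 3 * aa_end
        if end > genome_length:
            raise ValueError(
                f"aa interval [{aa_start}, {aa_end}] frame {frame} maps past "
                f"genome end ({end} > {genome_length})"
            )
        return NtInterval(start, end, "+")
    offset = frame - 4
    rc_start = offset + 3 * (aa_start - 1) + 1
    rc_end = offset + 3 * aa_end
    if rc_end > genome_length:
        raise ValueError(
            f"aa interval [{aa_start}, {aa_end}] frame {frame} maps past "
            f"genome end ({rc_end} > {genome_length})"
        )
    return NtInterval(genome_length - rc_end + 1, genome_length - rc_start + 1, "-")


def write_frame_fasta(
    genomes: Iterable[GenomeRecord], path: Union[str, Path]
) -> None:
    """Write all six frame translations as FASTA with ``<id>_frame<k>`` headers.

    This is the input shape expected by an external ``hmmsearch`` run whose
    domain table is re-ingested by the hit-parsing module.
    """
    with open(path, "w") as fh:
        for genome in genomes:
            for ft in six_frame_translate(genome):
                fh.write(f">{ft.genome_id}_frame{ft.frame}\n{ft.aa_sequence}\n")
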