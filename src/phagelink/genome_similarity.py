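"""Genome-pair identity: ANI/AAI parsers plus lightweight internal estimators.

Whole-genome relatedness enters the feature set as the mean Average
Nucleotide Identity (ANI) and mean Average Amino-acid Identity (AAI) over
the genomes where a group pair co-occurs.  At scale these come from fastANI
and CompareM output tables, for which parsers are provided.  For desk-scale
and synthetic work the module also carries internal estimators — a
fragment/k-mer ANI approximation and a reciprocal-best-match AAI over global
alignments.  These are approximations, not reimplementations of the
external tools; when parsed tool output is available it takes precedence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import edlib
import numpy as np

from .sequence_io import GenomeRecord

__all__ = [
    "IdentityMatrix",
    "parse_fastani",
    "parse_comparem_aai",
    "estimate_ani",
    "estimate_aai",
    "write_identity_tsv",
    "read_identity_tsv",
]

#: Pairs below this percent identity are ignored by the AAI estimator,
#: mirroring the usual twilight-zone floor in AAI practice.
AAI_IDENTITY_FLOOR = 30.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity lookup for genome pairs (possibly sparse).

    Inserting both directions of a pair stores their mean.  The diagonal is
    implicitly 100.
    """

    kind: str  # "ANI" or "AAI"
    _values: dict[tuple[str, str], float] = field(default_factory=dict)
    _n: dict[tuple[str, str], int] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, percent: float) -> None:
        if not (0.0 <= percent <= 100.0):
            raise ValueError(f"identity {percent} outside [0, 100] for ({a}, {b})")
        key = self._key(a, b)
        n = self._n.get(key, 0)
        prev = self._values.get(key, 0.0)
        self._values[key] = (prev * n + percent) / (n + 1)
        self._n[key] = n + 1

    def get(self, a: str, b: str) -> float | None:
        if a == b:
            return 100.0
        return self._values.get(self._key(a, b))

    def __len__(self) -> int:
        return len(self._values)

    def items(self) -> Iterable[tuple[tuple[str, str], float]]:
        return sorted(self._values.items())


def _strip_sequence_extensions(path_str: str) -> str:
    name = Path(path_str).name
    while True:
        stem, dot, ext = name.rpartition(".")
        if dot and ext.lower() in {"gz", "fa", "fna", "fasta", "fsa"}:
            name = stem
        else:
            return name


def parse_fastani(path: Union[str, Path]) -> IdentityMatrix:
    """Parse fastANI many-to-many output (query, ref, ANI, mapped, total)."""
    matrix = IdentityMatrix(kind="ANI")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                ani = float(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric ANI {fields[2]!r}")
            a = _strip_sequence_extensions(fields[0])
            b = _strip_sequence_extensions(fields[1])
            if a != b:
                matrix.set(a, b, ani)
    return matrix


def parse_comparem_aai(path: Union[str, Path]) -> IdentityMatrix:
    """Parse a CompareM ``aai_wf`` summary TSV (genome A, ..., mean AAI)."""
    matrix = IdentityMatrix(kind="AAI")
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return matrix
        lowered = [h.strip().lower().lstrip("#").strip() for h in header]
        try:
            mean_col = next(i for i, h in enumerate(lowered) if "mean aai" in h)
        except StopIteration:
            raise ValueError(f"{path}: no 'Mean AAI' column in header {header}")
        a_col = next(i for i, h in enumerate(lowered) if "genome" in h)
        b_col = next(
            i for i, h in enumerate(lowered) if "genome" in h and i != a_col
        )
        for lineno, fields in enumerate(reader, start=2):
            if not fields or not any(fields):
                continue
            try:
                aai = float(fields[mean_col])
            except (IndexError, ValueError):
                raise ValueError(f"{path}:{lineno}: malformed mean-AAI field")
            a = _strip_sequence_extensions(fields[a_col])
            b = _strip_sequence_extensions(fields[b_col])
            if a != b:
                matrix.set(a, b, aai)
    return matrix


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        pos.setdefault(seq[i : i + k], []).append(i)
    return pos


def _ungapped_identity(frag: np.ndarray, target: np.ndarray, offset: int) -> float:
    """Identity of ``frag`` against ``target`` aligned at ``offset``.

    Positions falling outside the target count as mismatches, so the
    denominator is always the full fragment length.
    """
    flen = len(frag)
    t_start = max(0, offset)
    t_end = min(len(target), offset + flen)
    if t_end <= t_start:
        return 0.0
    f_start = t_start - offset
    matches = int(
        np.count_nonzero(frag[f_start : f_start + (t_end - t_start)] == target[t_start:t_end])
    )
    return matches / flen


def estimate_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    k: int = 16,
    fragment_len: int = 1000,
) -> float | None:
    """Approximate ANI of two genomes by fragment mapping.

    Genome ``a`` is chopped into non-overlapping fragments of
    ``fragment_len``; each fragment is seeded against ``b`` (both strands)
    with exact k-mers, candidate offsets are ranked by seed votes, and the
    best ungapped identity over the top offsets is kept.  The result is the
    mean identity over fragments with at least one seed, in percent, or
    ``None`` if no fragment seeds.  The scheme is not exactly symmetric in
    its arguments; deviations stay within a couple of percentage points on
    closely related genomes.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    target_fwd = b.sequence
    target_rev = target_fwd.translate(_COMPLEMENT)[::-1]
    indexes = {
        "+": _kmer_positions(target_fwd, k),
        "-": _kmer_positions(target_rev, k),
    }
    arrays = {
        "+": np.frombuffer(target_fwd.encode(), dtype=np.uint8),
        "-": np.frombuffer(target_rev.encode(), dtype=np.uint8),
    }
    identities: list[float] = []
    n_frags = len(a.sequence) // fragment_len
    for fi in range(max(n_frags, 1 if len(a.sequence) >= k else 0)):
        frag = a.sequence[fi * fragment_len : (fi + 1) * fragment_len]
        if len(frag) < k:
            continue
        frag_arr = np.frombuffer(frag.encode(), dtype=np.uint8)
        best = None
        for strand in ("+", "-"):
            votes: dict[int, int] = {}
            idx = indexes[strand]
            for i in range(0, len(frag) - k + 1):
                for j in idx.get(frag[i : i + k], ()):
                    off = j - i
                    votes[off] = votes.get(off, 0) + 1
            for off, _ in sorted(votes.items(), key=lambda kv: -kv[1])[:3]:
                ident = _ungapped_identity(frag_arr, arrays[strand], off)
                if best is None or ident > best:
                    best = ident
        if best is not None:
            identities.append(best)
    if not identities:
        return None
    return 100.0 * float(np.mean(identities))


def _pairwise_identity(p: str, q: str) -> float:
    """Global-alignment identity: 1 - edit distance / max length."""
    ed = edlib.align(p, q, mode="NW", task="distance")["editDistance"]
    return 1.0 - ed / max(len(p), len(q))


def estimate_aai(
    a_proteins: Sequence[str] | Mapping[str, str],
    b_proteins: Sequence[str] | Mapping[str, str],
) -> float | None:
    """Approximate AAI as the mean identity of reciprocal best matches.

    Each protein of one set is matched to its highest-identity partner in
    the other (global alignment identity); reciprocal pairs above the 30%
    identity floor contribute.  Returns percent, or ``None`` if no
    reciprocal match clears the floor or either set is empty.
    """
    seqs_a = list(a_proteins.values()) if isinstance(a_proteins, Mapping) else list(a_proteins)
    seqs_b = list(b_proteins.values()) if isinstance(b_proteins, Mapping) else list(b_proteins)
    if not seqs_a or not seqs_b:
        return None
    ident = np.array(
        [[_pairwise_identity(p, q) for q in seqs_b] for p in seqs_a]
    )
    best_for_a = ident.argmax(axis=1)
    best_for_b = ident.argmax(axis=0)
    values = [
        100.0 * ident[i, j]
        for i, j in enumerate(best_for_a)
        if best_for_b[j] == i and 100.0 * ident[i, j] >= AAI_IDENTITY_FLOOR
    ]
    if not values:
        return None
    return float(np.mean(values))


def write_identity_tsv(matrix: IdentityMatrix, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome_a", "genome_b", "percent_identity"])
        for (a, b), value in matrix.items():
            writer.writerow([a, b, f"{value:.4f}"])


def read_identity_tsv(path: Union[str, Path], kind: str) -> IdentityMatrix:
    matrix = IdentityMatrix(kind=kind)
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            matrix.set(row["genome_a"], row["genome_b"], float(row["percent_identity"]))
    return matrix
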