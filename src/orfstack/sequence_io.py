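"""Reading and writing sequence formats, and cutting genomes into fragments.

FASTA is read through Biopython and normalized to the uppercase DNA
alphabet {A, C, G, T, N} (RNA ``U`` is mapped to ``T``).  GFF3 annotations
are 1-based inclusive on disk, per the standard, and 0-based half-open in
memory.  ``fragment_genome`` emulates shotgun sampling of a genome into
fixed-length reads at a chosen fold coverage.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.iterators import DataIterator

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str


@dataclasses.dataclass(frozen=True)
class Fragment:
    """A fixed-length piece of DNA, e.g. a simulated sequencing read.

    ``source`` records provenance on the parent genome as
    ``(genome_id, start, strand)`` with a 0-based start on the forward
    genome strand; strand ``-`` means the fragment sequence is the reverse
    complement of the genome interval.
    """

    id: str
    sequence: str
    source: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"fragment {self.id!r}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"fragment {self.id!r}: sequence must be uppercase")

    @property
    def L(self) -> int:
        """Fragment length in bp."""
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene interval, 0-based half-open on the genome."""

    genome_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"annotation strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ParseError(
            f"record {record_id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file into ordered, normalized records.

    Sequences are uppercased, U is mapped to T and any character outside
    {A, C, G, T, N} raises :class:`ParseError`.  Empty records are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[FastaRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        records.append(FastaRecord(rec.id, _normalize_sequence(str(rec.seq), rec.id)))
    if not records:
        with open(path) as fh:
            head = fh.read(1)
        if head and head != ">":
            raise ParseError(f"{path}: not a FASTA file (missing '>' header)")
    return records


def write_fasta(records: Iterable[FastaRecord | Fragment], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read gene/CDS features from a GFF3 file.

    On-disk coordinates are 1-based inclusive; the returned annotations
    are 0-based half-open.  Features other than ``gene``/``CDS`` are
    ignored.  A missing strand ('.') or an inverted interval is a
    :class:`ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    annotations: list[GeneAnnotation] = []
    for feature in DataIterator(str(path)):
        if feature.featuretype not in {"gene", "CDS"}:
            continue
        if feature.strand not in {"+", "-"}:
            raise ParseError(
                f"{path}: feature at {feature.seqid}:{feature.start}-{feature.end} "
                f"has unsupported strand {feature.strand!r}"
            )
        if feature.end < feature.start:
            raise ParseError(
                f"{path}: feature at {feature.seqid}:{feature.start}-{feature.end} has end < start"
            )
        annotations.append(
            GeneAnnotation(
                genome_id=feature.seqid,
                start=feature.start - 1,
                end=feature.end,
                strand=feature.strand,
            )
        )
    return annotations


def write_gff3(annotations: Sequence[GeneAnnotation], path: str | Path, source: str = "orfstack") -> None:
    """Write annotations as GFF3 ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ann in enumerate(annotations):
            fh.write(
                f"{ann.genome_id}\t{source}\tgene\t{ann.start + 1}\t{ann.end}\t.\t"
                f"{ann.strand}\t0\tID=gene{i:05d}\n"
            )


def fragment_genome(
    genome: FastaRecord | tuple[str, str],
    frag_len: int,
    coverage: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> list[Fragment]:
    """Randomly sample fixed-length fragments from a genome.

    Returns ``floor(coverage * genome_len / frag_len)`` fragments of
    exactly ``frag_len`` bp.  Start positions are uniform with
    replacement and each fragment's strand is '+' or '-' with equal
    probability (reads come from either strand); '-' fragments carry the
    reverse complement.  Deterministic given ``seed``.
    """
    if isinstance(genome, tuple):
        genome = FastaRecord(*genome)
    if frag_len < 1:
        raise ValueError("frag_len must be >= 1")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    glen = len(genome.sequence)
    if glen < frag_len:
        raise ValueError(f"genome {genome.id!r} ({glen} bp) shorter than frag_len {frag_len}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(coverage * glen // frag_len)
    starts = rng.integers(0, glen - frag_len + 1, size=n)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    fragments = []
    for i, (s, strand) in enumerate(zip(starts, strands)):
        s = int(s)
        seq = genome.sequence[s : s + frag_len]
        if strand == "-":
            seq = reverse_complement(seq)
        fragments.append(
            Fragment(
                id=f"{genome.id}|frag{i:06d}|{s}|{strand}",
                sequence=seq,
                source=(genome.id, s, str(strand)),
            )
        )
    return fragments
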