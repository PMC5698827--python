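"""Candidate ORF enumeration in all six frames of a fragment.

Short sequencing fragments truncate genes, so besides complete ORFs
(start codon through stop codon) the scanner emits incomplete ORFs that
run off the upstream end, the downstream end, or both ends of the
fragment.  When fragment provenance and a genome annotation are
available, ``label_orf`` assigns coding/noncoding labels by in-frame,
same-strand overlap with annotated genes.

Scanning rules, per (strand, frame), reading codons 5'->3' on the coding
strand:

* complete ORF: first start codon after the previous stop, through the
  next stop codon inclusive;
* upstream-incomplete: the frame's first codon through the first stop
  codon inclusive, when no start codon precedes that stop;
* downstream-incomplete: a start codon through the frame's last whole
  codon, when no stop follows;
* both-ends-incomplete: all whole codons of the frame, when the frame
  contains neither a stop nor a start codon.

Per stop-to-stop segment at most one (the longest) ORF is emitted;
nested ORFs starting at later in-frame starts are not.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from orfstack.sequence_io import Fragment, GeneAnnotation, reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

#: an ORF is dropped when more than this fraction of its codons contain N
MAX_AMBIGUOUS_FRAC = 0.10

TSV_COLUMNS = (
    "fragment_id",
    "strand",
    "frame",
    "start",
    "end",
    "has_start",
    "has_stop",
    "l",
    "L",
    "label",
)


@dataclasses.dataclass
class OrfCandidate:
    """A candidate ORF within a fragment.

    ``start``/``end`` are 0-based half-open on the fragment's forward
    strand; ``frame`` is the codon offset in the reading direction
    (i.e. on the reverse complement for strand '-').  ``codons`` are read
    5'->3' on the coding strand and include the stop codon when present.
    """

    fragment_id: str
    strand: str
    frame: int
    start: int
    end: int
    codons: list[str]
    has_start: bool
    has_stop: bool
    L: int
    label: str = "unknown"
    source: tuple[str, int, str] | None = None

    @property
    def l(self) -> int:
        """ORF length in bp (includes the stop codon when present)."""
        return self.end - self.start

    @property
    def complete(self) -> bool:
        return self.has_start and self.has_stop

    @property
    def countable_codons(self) -> list[str]:
        """Codons free of ambiguous bases; the ones feature counts use."""
        return [c for c in self.codons if "N" not in c]

    def genome_interval(self) -> tuple[str, int, int, str]:
        """Map the ORF to genome coordinates via its fragment provenance.

        Returns ``(genome_id, start, end, strand)`` with 0-based
        half-open coordinates on the forward genome strand.
        """
        if self.source is None:
            raise ValueError(
                f"ORF in fragment {self.fragment_id!r} has no source provenance; cannot map to genome"
            )
        genome_id, frag_start, frag_strand = self.source
        if frag_strand == "+":
            g_start = frag_start + self.start
            g_end = frag_start + self.end
            g_strand = self.strand
        else:
            g_start = frag_start + self.L - self.end
            g_end = frag_start + self.L - self.start
            g_strand = "-" if self.strand == "+" else "+"
        return genome_id, g_start, g_end, g_strand


def _scan_frame(
    reading_seq: str,
    frame: int,
    start_codons: frozenset[str],
) -> list[tuple[int, int, bool, bool]]:
    """Scan one frame; return (first_codon, last_codon, has_start, has_stop) spans.

    Codon indices are inclusive and refer to ``reading_seq[frame:]``.
    """
    n_codons = (len(reading_seq) - frame) // 3
    if n_codons <= 0:
        return []
    codons = [reading_seq[frame + 3 * k : frame + 3 * k + 3] for k in range(n_codons)]
    spans: list[tuple[int, int, bool, bool]] = []
    prev_stop = -1
    saw_stop = False
    for k, codon in enumerate(codons):
        if codon in STOP_CODONS:
            segment = range(prev_stop + 1, k)
            first_start = next((j for j in segment if codons[j] in start_codons), None)
            if first_start is not None:
                spans.append((first_start, k, True, True))
            elif not saw_stop:
                # leading segment truncated upstream by the fragment edge
                if k >= prev_stop + 1:
                    spans.append((0, k, False, True))
            saw_stop = True
            prev_stop = k
    tail = range(prev_stop + 1, n_codons)
    first_start = next((j for j in tail if codons[j] in start_codons), None)
    if first_start is not None:
        spans.append((first_start, n_codons - 1, True, False))
    elif not saw_stop and n_codons > 0:
        spans.append((0, n_codons - 1, False, False))
    return spans


def extract_orfs(
    fragment: Fragment,
    min_len: int = 60,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> list[OrfCandidate]:
    """Enumerate candidate ORFs in all six frames of a fragment.

    ORFs shorter than ``min_len`` bp are discarded, as are ORFs whose
    fraction of ambiguous (N-containing) codons exceeds
    :data:`MAX_AMBIGUOUS_FRAC`.
    """
    start_codons = frozenset(c.upper().replace("U", "T") for c in start_codons)
    L = fragment.L
    forward = fragment.sequence
    reverse = reverse_complement(forward)
    orfs: list[OrfCandidate] = []
    for strand, reading_seq in (("+", forward), ("-", reverse)):
        for frame in range(3):
            for first, last, has_start, has_stop in _scan_frame(reading_seq, frame, start_codons):
                n_codons = last - first + 1
                length = 3 * n_codons
                if length < min_len:
                    continue
                codons = [
                    reading_seq[frame + 3 * k : frame + 3 * k + 3]
                    for k in range(first, last + 1)
                ]
                n_ambiguous = sum(1 for c in codons if "N" in c)
                if n_ambiguous > MAX_AMBIGUOUS_FRAC * n_codons:
                    continue
                r_start = frame + 3 * first
                r_end = frame + 3 * (last + 1)
                if strand == "+":
                    start, end = r_start, r_end
                else:
                    start, end = L - r_end, L - r_start
                orfs.append(
                    OrfCandidate(
                        fragment_id=fragment.id,
                        strand=strand,
                        frame=frame,
                        start=start,
                        end=end,
                        codons=codons,
                        has_start=has_start,
                        has_stop=has_stop,
                        L=L,
                        source=fragment.source,
                    )
                )
    return orfs


def label_orf(
    orf: OrfCandidate,
    annotations: Sequence[GeneAnnotation],
    min_overlap_frac: float = 0.8,
) -> str:
    """Label an ORF coding/noncoding against a genome annotation.

    An ORF is coding iff, mapped to genome coordinates, it overlaps an
    annotated gene on the same strand and in the same reading frame over
    at least ``min_overlap_frac`` of the ORF's length.  Reading frame is
    compared at the codon level: on '+' the ORF's genome start must be a
    codon boundary of the gene, on '-' its genome end must be.
    """
    genome_id, o_start, o_end, o_strand = orf.genome_interval()
    o_len = o_end - o_start
    for gene in annotations:
        if gene.genome_id != genome_id or gene.strand != o_strand:
            continue
        overlap = min(gene.end, o_end) - max(gene.start, o_start)
        if overlap <= 0 or overlap < min_overlap_frac * o_len:
            continue
        if o_strand == "+":
            in_frame = (o_start - gene.start) % 3 == 0
        else:
            in_frame = (gene.end - o_end) % 3 == 0
        if in_frame:
            return "coding"
    return "noncoding"


def label_orfs(
    orfs: Iterable[OrfCandidate],
    annotations: Sequence[GeneAnnotation],
    min_overlap_frac: float = 0.8,
) -> None:
    """Label ORFs in place (see :func:`label_orf`)."""
    for orf in orfs:
        orf.label = label_orf(orf, annotations, min_overlap_frac)


def orfs_to_rows(orfs: Iterable[OrfCandidate]) -> list[dict]:
    """Tabular view of ORFs matching :data:`TSV_COLUMNS`."""
    return [
        {
            "fragment_id": o.fragment_id,
            "strand": o.strand,
            "frame": o.frame,
            "start": o.start,
            "end": o.end,
            "has_start": o.has_start,
            "has_stop": o.has_stop,
            "l": o.l,
            "L": o.L,
            "label": o.label,
        }
        for o in orfs
    ]
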