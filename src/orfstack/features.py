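"""ORF feature descriptors and their fusion into one 119-dim vector.

Four descriptors are computed per candidate ORF and concatenated:

* ORF coverage (1): the length ratio ``l / L`` of the ORF to its parent
  fragment — coding ORFs tend to fill more of a read than spurious ones.
* Monocodon usage, MCU (64): codon frequencies over all 64 codons
  (stop codons included) in fixed lexicographic DNA order AAA..TTT.
* Monoamino acid usage, MAU (21): frequencies of the 20 amino acids plus
  STOP, obtained from the codons through the standard genetic code.
* Z-curve parameters: linear purine/pyrimidine (x), amino/keto (y) and
  weak/strong (z) contrasts of nucleotide frequencies, computed per codon
  position (ZCPS, 9) and for phase-specific dinucleotides at codon
  positions 1-2 and 2-3 (ZCPD, 24).

All frequencies are over "countable" codons, i.e. codons free of
ambiguous bases; the stop codon, when present, counts like any codon.
The fused vector is ``[ORFC | MCU | MAU | ZCPS | ZCPD]`` = 1 + 64 + 21 +
9 + 24 = 119 components, in that fixed order.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from orfstack.orf_finder import OrfCandidate

#: the 64 codons in lexicographic DNA order AAA, AAC, ..., TTT
CODONS: tuple[str, ...] = tuple("".join(c) for c in itertools.product("ACGT", repeat=3))
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

#: the 20 amino acids (alphabetical one-letter code) plus STOP
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY") + ("STOP",)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _build_codon_to_aa() -> np.ndarray:
    """64 -> 21 aggregation matrix of the standard genetic code."""
    M = np.zeros((21, 64))
    for i, codon in enumerate(CODONS):
        if codon in _STANDARD_TABLE.stop_codons:
            aa = "STOP"
        else:
            aa = _STANDARD_TABLE.forward_table[codon]
        M[_AA_INDEX[aa], i] = 1.0
    return M


#: fixed 21x64 matrix with MAU = CODON_TO_AA @ MCU for every ORF
CODON_TO_AA: np.ndarray = _build_codon_to_aa()

NUCLEOTIDES = "ACGT"
_DINUCLEOTIDES: tuple[str, ...] = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2))

FEATURE_GROUPS: dict[str, int] = {"orfc": 1, "mcu": 64, "mau": 21, "zcps": 9, "zcpd": 24}
N_FEATURES = sum(FEATURE_GROUPS.values())  # 119


def _feature_names() -> tuple[str, ...]:
    names = ["orfc"]
    names += [f"mcu_{c}" for c in CODONS]
    names += [f"mau_{a}" for a in AMINO_ACIDS]
    names += [f"zcps_{v}{i}" for i in (1, 2, 3) for v in ("x", "y", "z")]
    names += [
        f"zcpd_{v}{k}_{m}" for k in ("12", "23") for m in NUCLEOTIDES for v in ("x", "y", "z")
    ]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _feature_names()


def group_slices() -> dict[str, slice]:
    """Column slices of each descriptor group within the fused vector."""
    out, offset = {}, 0
    for name, width in FEATURE_GROUPS.items():
        out[name] = slice(offset, offset + width)
        offset += width
    return out


@dataclasses.dataclass(frozen=True)
class CodonPositionCounts:
    """Per-codon-position nucleotide and phase dinucleotide frequencies.

    ``mono[i]`` holds the A/C/G/T frequencies at codon position i+1;
    ``dinuc["12"]`` / ``dinuc["23"]`` hold the 16 dinucleotide
    frequencies at codon positions 1-2 and 2-3.
    """

    mono: np.ndarray  # 3 x 4
    dinuc: dict[str, np.ndarray]  # phase -> length-16 vector


def _countable(orf_or_codons: OrfCandidate | Sequence[str]) -> list[str]:
    if isinstance(orf_or_codons, OrfCandidate):
        codons = orf_or_codons.countable_codons
    else:
        codons = [c for c in orf_or_codons if "N" not in c]
    if not codons:
        raise ValueError("no countable (N-free) codons")
    return codons


def codon_position_counts(orf_or_codons: OrfCandidate | Sequence[str]) -> CodonPositionCounts:
    codons = _countable(orf_or_codons)
    n = len(codons)
    mono = np.zeros((3, 4))
    d12 = np.zeros(16)
    d23 = np.zeros(16)
    nt_idx = {b: i for i, b in enumerate(NUCLEOTIDES)}
    di_idx = {d: i for i, d in enumerate(_DINUCLEOTIDES)}
    for codon in codons:
        for pos in range(3):
            mono[pos, nt_idx[codon[pos]]] += 1
        d12[di_idx[codon[0:2]]] += 1
        d23[di_idx[codon[1:3]]] += 1
    return CodonPositionCounts(mono=mono / n, dinuc={"12": d12 / n, "23": d23 / n})


def orf_coverage(orf: OrfCandidate) -> float:
    """Length proportion l / L of the ORF to its fragment."""
    if orf.l > orf.L:
        raise ValueError(f"ORF length {orf.l} exceeds fragment length {orf.L}")
    if orf.l < 1:
        raise ValueError("empty ORF")
    return orf.l / orf.L


def monocodon_usage(orf_or_codons: OrfCandidate | Sequence[str]) -> np.ndarray:
    """64-dim codon frequency vector (order AAA..TTT, stops included)."""
    codons = _countable(orf_or_codons)
    counts = np.zeros(64)
    for codon in codons:
        counts[_CODON_INDEX[codon]] += 1
    return counts / len(codons)


def monoamino_usage(orf_or_codons: OrfCandidate | Sequence[str]) -> np.ndarray:
    """21-dim amino acid (+STOP) frequency vector via the standard code."""
    return CODON_TO_AA @ monocodon_usage(orf_or_codons)


def zcurve_position_specific(counts: CodonPositionCounts) -> np.ndarray:
    """9 Z-curve contrasts of codon-position-specific base frequencies.

    For each codon position i: x = (a+g)-(c+t), y = (a+c)-(g+t),
    z = (a+t)-(g+c); output order (x1,y1,z1, x2,y2,z2, x3,y3,z3).
    """
    out = np.empty(9)
    for i in range(3):
        a, c, g, t = counts.mono[i]
        out[3 * i : 3 * i + 3] = ((a + g) - (c + t), (a + c) - (g + t), (a + t) - (g + c))
    return out


def zcurve_phase_dinucleotide(counts: CodonPositionCounts) -> np.ndarray:
    """24 Z-curve contrasts of phase-specific dinucleotide frequencies.

    For phases k in {12, 23} and first base M in {A,C,G,T}:
    x = [p(MA)+p(MG)]-[p(MC)+p(MT)], y = [p(MA)+p(MC)]-[p(MG)+p(MT)],
    z = [p(MA)+p(MT)]-[p(MC)+p(MG)]; all (x,y,z) for M = A,C,G,T at
    phase 12, then phase 23.
    """
    di_idx = {d: i for i, d in enumerate(_DINUCLEOTIDES)}
    out = np.empty(24)
    pos = 0
    for phase in ("12", "23"):
        p = counts.dinuc[phase]
        for m in NUCLEOTIDES:
            pa, pc, pg, pt = (p[di_idx[m + b]] for b in NUCLEOTIDES)
            out[pos : pos + 3] = ((pa + pg) - (pc + pt), (pa + pc) - (pg + pt), (pa + pt) - (pc + pg))
            pos += 3
    return out


def fuse_features(orf: OrfCandidate) -> np.ndarray:
    """Concatenate [ORFC | MCU | MAU | ZCPS | ZCPD] into one 119-vector."""
    counts = codon_position_counts(orf)
    mcu = monocodon_usage(orf)
    return np.concatenate(
        [
            [orf_coverage(orf)],
            mcu,
            CODON_TO_AA @ mcu,
            zcurve_position_specific(counts),
            zcurve_phase_dinucleotide(counts),
        ]
    )


def feature_matrix(orfs: Iterable[OrfCandidate]) -> np.ndarray:
    """Stack fused feature vectors into an (n_orfs, 119) matrix."""
    orfs = list(orfs)
    X = np.empty((len(orfs), N_FEATURES))
    for i, orf in enumerate(orfs):
        X[i] = fuse_features(orf)
    return X
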