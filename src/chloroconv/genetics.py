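"""Genetic-code tables and codon bookkeeping for the M0 codon model.

Translation table 11 (bacterial / plant plastid) is the default; for the
61 sense codons it is identical to the standard code (the tables differ
only in permissive start codons, which play no role here).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

NUCLEOTIDES = "TCAG"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GAP = "-"

# Standard genetic code in TCAG order; '*' marks stops.  Table 11 shares
# this sense-codon translation.
_CODE_STRING = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)

ALL_CODONS = tuple(
    n1 + n2 + n3 for n1 in NUCLEOTIDES for n2 in NUCLEOTIDES for n3 in NUCLEOTIDES
)

CODON_TO_AA = dict(zip(ALL_CODONS, _CODE_STRING))

STOP_CODONS = tuple(c for c, aa in CODON_TO_AA.items() if aa == "*")

SENSE_CODONS = tuple(c for c in ALL_CODONS if CODON_TO_AA[c] != "*")

SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

N_SENSE = len(SENSE_CODONS)  # 61


def translate_codon(codon: str) -> str:
    """Translate one codon; '---' maps to the gap residue.

    Raises ValueError for stop codons, partially gapped codons and
    unknown characters.
    """
    codon = codon.upper()
    if codon == GAP * 3:
        return GAP
    if GAP in codon:
        raise ValueError(f"partially gapped codon {codon!r}")
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        raise ValueError(f"unknown codon {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r}")
    return aa


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@lru_cache(maxsize=1)
def codon_pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Structural masks over sense-codon pairs for building M0 rate matrices.

    Returns (single_nt, is_transition, is_synonymous), three boolean
    (61, 61) arrays.  single_nt marks pairs differing at exactly one
    codon position; the other two are meaningful only where single_nt.
    """
    n = N_SENSE
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    synonymous = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = frozenset(diffs[0]) in _TRANSITIONS
            synonymous[i, j] = CODON_TO_AA[ci] == CODON_TO_AA[cj]
    return single, transition, synonymous


@lru_cache(maxsize=1)
def aa_collapse_matrix() -> np.ndarray:
    """(61, 20) indicator mapping sense codons onto amino acids."""
    m = np.zeros((N_SENSE, len(AMINO_ACIDS)))
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    for i, codon in enumerate(SENSE_CODONS):
        m[i, aa_index[CODON_TO_AA[codon]]] = 1.0
    return m


def codons_for_aa(aa: str) -> tuple[str, ...]:
    return tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
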