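"""Genetic-code utilities shared across the package.

Everything here is derived once, at import time, from the universal (NCBI
table 1) genetic code as shipped with Biopython: codon -> amino acid lookup,
per-position degeneracy classes, and the single-nucleotide neighborhood of
each codon annotated with synonymous / transition / stop status.
"""

from __future__ import annotations

from typing import NamedTuple

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with ``*`` for the three stop codons.
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

# Degeneracy classes for codon positions.  The class counts how many of the
# three alternative nucleotides at that position leave the amino acid
# unchanged; a change to a stop codon is never synonymous.
ND = "nd"          # nondegenerate: every change alters the protein
TWOFOLD = "2f"
THREEFOLD = "3f"
FOURFOLD = "4d"    # fourfold degenerate: no change alters the protein
_DEG_BY_COUNT = {0: ND, 1: TWOFOLD, 2: THREEFOLD, 3: FOURFOLD}


def is_transition(a: str, b: str) -> bool:
    """True if a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return a != b and (a in PURINES) == (b in PURINES)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon, ``*`` for stops, ``X`` if ambiguous."""
    return CODON_TO_AA.get(codon, "X")


class CodonChange(NamedTuple):
    pos: int          # 0, 1 or 2 within the codon
    alt: str          # replacement nucleotide
    new_codon: str
    synonymous: bool  # same amino acid (stop targets are never synonymous)
    transition: bool
    to_stop: bool


def _neighbors(codon: str) -> tuple[CodonChange, ...]:
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1:]
            new_aa = CODON_TO_AA[new]
            out.append(CodonChange(
                pos, alt, new,
                synonymous=(new_aa == aa and new_aa != "*"),
                transition=is_transition(codon[pos], alt),
                to_stop=(new_aa == "*"),
            ))
    return tuple(out)


#: codon -> 9 single-nucleotide neighbors with change annotations.
CODON_NEIGHBORS: dict[str, tuple[CodonChange, ...]] = {
    c: _neighbors(c) for c in CODON_TO_AA
}


def degeneracy_class(codon: str, pos: int) -> str | None:
    """Degeneracy class of ``pos`` within ``codon``; None for stop/ambiguous codons."""
    if codon in STOP_CODONS or codon not in CODON_TO_AA:
        return None
    n_syn = sum(1 for ch in CODON_NEIGHBORS[codon]
                if ch.pos == pos and ch.synonymous)
    return _DEG_BY_COUNT[n_syn]


#: (codon, pos) -> degeneracy class for all sense codons.
DEGENERACY: dict[tuple[str, int], str] = {
    (c, p): degeneracy_class(c, p)  # type: ignore[misc]
    for c in SENSE_CODONS for p in range(3)
}


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string codon by codon (no stop scanning)."""
    return "".join(translate_codon(seq[i:i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3))


def has_internal_stop(cds: str) -> bool:
    """True if any codon before the final one is a stop codon."""
    n = len(cds) - len(cds) % 3
    return any(is_stop(cds[i:i + 3]) for i in range(0, max(n - 3, 0), 3))


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
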