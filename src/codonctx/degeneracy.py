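"""Genetic code tables and four-fold degeneracy classification.

A third codon position is four-fold degenerate (FFD) when every nucleotide in
that position yields the same amino acid, which under the standard code holds
for exactly eight codon families (alanine GCN, arginine CGN, glycine GGN,
leucine CTN, proline CCN, threonine ACN, serine TCN, valine GTN).  Context-
dependent models restricted to FFD sites classify each third position from the
codon state at the *start* of a branch, so the same alignment column can be
FFD on one branch and not on another.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

NUCLEOTIDES = "ACGT"
NUC_CODE = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: Standard (NCBI table 1) genetic code, codon -> one-letter amino acid or "*".
_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class IndeterminateCodon(ValueError):
    """Raised when degeneracy cannot be decided from ambiguous bases."""


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: mapping from the 64 codons to amino acids or ``*``.

    Parameters
    ----------
    table : dict
        Codon (upper-case, T not U) to one-letter amino acid; stops are ``*``.
    table_id : int
        NCBI translation-table identifier, for reporting.
    """

    table: dict
    table_id: int = 1

    def __post_init__(self):
        if len(self.table) != 64:
            raise ValueError(f"genetic code needs 64 entries, got {len(self.table)}")

    @property
    def stop_codons(self) -> tuple:
        return tuple(sorted(c for c, aa in self.table.items() if aa == "*"))

    @property
    def sense_codons(self) -> tuple:
        """The sense codons in alphabetical (A<C<G<T) order; 61 for table 1."""
        return tuple(
            "".join(c) for c in product(NUCLEOTIDES, repeat=3)
            if self.table["".join(c)] != "*"
        )

    def translate(self, codon: str) -> str:
        return self.table[codon.upper().replace("U", "T")]


def get_genetic_code(table_id: int = 1) -> GeneticCode:
    """Return a genetic code by NCBI translation-table id (only table 1 built in)."""
    if table_id != 1:
        raise ValueError(f"unsupported translation table {table_id}; only 1 (standard)")
    return GeneticCode(dict(_STANDARD_TABLE), 1)


STANDARD_CODE = get_genetic_code(1)


def is_fourfold_prefix(first: str, second: str, code: GeneticCode = STANDARD_CODE) -> bool:
    """True iff codons ``first+second+N`` all code for one identical amino acid.

    ``first``/``second`` must be unambiguous nucleotides; ambiguity symbols
    raise :class:`IndeterminateCodon` so the caller can decide on a fallback.
    """
    first, second = first.upper().replace("U", "T"), second.upper().replace("U", "T")
    if first not in NUC_CODE or second not in NUC_CODE:
        raise IndeterminateCodon(f"cannot classify prefix {first}{second!r}")
    aas = {code.table[first + second + b] for b in NUCLEOTIDES}
    return len(aas) == 1 and "*" not in aas


def fourfold_prefix_table(code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Boolean lookup of length 16 indexed by ``4*code(first) + code(second)``."""
    tab = np.zeros(16, dtype=bool)
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            tab[4 * NUC_CODE[a] + NUC_CODE[b]] = is_fourfold_prefix(a, b, code)
    return tab


def classify_third_positions(parent_sequence, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Per-codon FFD mask for an in-frame sequence (the branch-start state).

    Accepts a string over ``ACGTUN-`` or an integer-coded array (A..T = 0..3,
    missing < 0).  Codons whose first two bases are ambiguous or missing are
    conservatively classified non-FFD, falling back to the independent
    third-position model.
    """
    if isinstance(parent_sequence, str):
        seq = parent_sequence.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        codes = np.array([NUC_CODE.get(b, -1) for b in seq], dtype=np.int8)
    else:
        codes = np.asarray(parent_sequence)
        if codes.shape[0] % 3:
            raise ValueError(f"sequence length {codes.shape[0]} not divisible by 3")
    tab = fourfold_prefix_table(code)
    first, second = codes[0::3], codes[1::3]
    ok = (first >= 0) & (second >= 0)
    mask = np.zeros(first.shape[0], dtype=bool)
    mask[ok] = tab[4 * first[ok].astype(int) + second[ok].astype(int)]
    return mask
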