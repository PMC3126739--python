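"""Grantham (1974) physicochemical distances between the 20 amino acids.

The distance combines composition, polarity and molecular volume of the side
chains; it ranges from 5 (Leu-Ile) to 215 (Cys-Trp).  The full symmetric
matrix is embedded as constant data from the published table and is used by
the Goldman-Yang codon model to penalise non-synonymous substitutions.
"""

from __future__ import annotations

import numpy as np

#: Amino acids in the order of the published table.
AMINO_ACIDS = "SRLPTAVGIFYCHQNKDEMW"

# Lower-triangle rows of the published table, one row per amino acid in
# AMINO_ACIDS order (row i lists distances to amino acids i+1..19).
_ROWS = [
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],
    [194, 83, 99, 143, 85, 160, 122, 36, 37],
    [174, 154, 139, 202, 154, 170, 196, 215],
    [24, 68, 32, 81, 40, 87, 115],
    [46, 53, 61, 29, 101, 130],
    [94, 23, 42, 142, 174],
    [101, 56, 95, 110],
    [45, 160, 181],
    [126, 152],
    [67],
]


def grantham_matrix() -> np.ndarray:
    """Return the 20x20 symmetric Grantham distance matrix.

    Rows/columns are ordered as :data:`AMINO_ACIDS`; the diagonal is zero.
    """
    d = np.zeros((20, 20))
    for i, row in enumerate(_ROWS):
        for k, value in enumerate(row):
            j = i + 1 + k
            d[i, j] = d[j, i] = float(value)
    return d


def grantham_distance(aa1: str, aa2: str) -> float:
    """Distance between two amino acids given as one-letter codes."""
    m = grantham_matrix()
    return float(m[AMINO_ACIDS.index(aa1), AMINO_ACIDS.index(aa2)])
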