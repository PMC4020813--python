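"""The 20-letter standard amino-acid alphabet and the 400 ordered dipeptides.

All composition vectors and scoring cards in this package are indexed
against these two orderings: residues alphabetically, dipeptides row-major
(first residue major, second residue minor), so pair ``(a, b)`` lives at
``20 * index(a) + index(b)``.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard residues, alphabetical by one-letter code."""

N_AA = 20
N_PAIRS = 400

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DIPEPTIDES: tuple[str, ...] = tuple(
    a + b for a in AMINO_ACIDS for b in AMINO_ACIDS
)
"""All 400 ordered residue pairs in row-major alphabetical order."""

PAIR_INDEX: dict[str, int] = {p: i for i, p in enumerate(DIPEPTIDES)}

# residues -> integer codes, 255 marks a non-standard letter
_CODE = np.full(128, 255, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _CODE[ord(_aa)] = _i


def encode(residues: str) -> np.ndarray:
    """Map a validated residue string to integer codes in ``[0, 20)``."""
    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted({c for c in residues if c not in AA_INDEX})
        raise ValueError(f"non-standard residue letters: {''.join(bad)}")
    return codes.astype(np.intp)
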