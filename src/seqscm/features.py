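"""Dipeptide and amino-acid composition features.

A sequence of length L yields 400 dipeptide fractions (overlapping adjacent
pairs, divisor L−1) or 20 residue fractions (divisor L); both sum to one.
Class-level compositions average the per-sequence vectors with equal weight
by default, so a long sequence does not dominate the class profile; pooled
residue counting is available for sensitivity checks.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, DIPEPTIDES, N_AA, N_PAIRS, encode
from .errors import FeatureError
from .seqio import ProteinSequence

__all__ = [
    "dipeptide_composition",
    "amino_acid_composition",
    "class_mean_composition",
    "composition_matrix",
    "composition_series",
]


def dipeptide_composition(seq: ProteinSequence) -> np.ndarray:
    """400-vector of overlapping dipeptide fractions for one sequence.

    Entry for pair ``(a, b)`` is the count of adjacent occurrences of
    ``a`` followed by ``b`` divided by ``L - 1``.
    """
    if len(seq) < 2:
        raise FeatureError(
            f"sequence {seq.id!r}: length {len(seq)} < 2, "
            "dipeptide composition undefined"
        )
    codes = encode(seq.residues)
    pair_idx = codes[:-1] * N_AA + codes[1:]
    counts = np.bincount(pair_idx, minlength=N_PAIRS).astype(float)
    return counts / (len(seq) - 1)


def amino_acid_composition(
    seq: ProteinSequence, *, percent: bool = False
) -> np.ndarray:
    """20-vector of residue fractions (or percentages) for one sequence."""
    if len(seq) < 1:
        raise FeatureError(f"sequence {seq.id!r}: empty")
    codes = encode(seq.residues)
    counts = np.bincount(codes, minlength=N_AA).astype(float)
    comp = counts / len(seq)
    return comp * 100.0 if percent else comp


def composition_matrix(seqs: Sequence[ProteinSequence]) -> np.ndarray:
    """Stack per-sequence dipeptide compositions into an ``(n, 400)`` matrix."""
    return np.array([dipeptide_composition(s) for s in seqs])


def class_mean_composition(
    seqs: Iterable[ProteinSequence],
    kind: str = "dipeptide",
    *,
    pooled: bool = False,
) -> np.ndarray:
    """Class-level composition of a set of sequences.

    Parameters
    ----------
    kind : {"dipeptide", "amino-acid"}
        Feature space of the result (400- or 20-vector).
    pooled : bool
        If False (default), average per-sequence composition vectors with
        equal weight. If True, pool raw counts over all sequences first,
        which weights sequences by their length.
    """
    seqs = list(seqs)
    if not seqs:
        raise FeatureError("empty sequence list")
    if kind == "dipeptide":
        per_seq = [dipeptide_composition(s) for s in seqs]
        if pooled:
            counts = np.sum(
                [v * (len(s) - 1) for v, s in zip(per_seq, seqs)], axis=0
            )
            return counts / counts.sum()
    elif kind == "amino-acid":
        per_seq = [amino_acid_composition(s) for s in seqs]
        if pooled:
            counts = np.sum(
                [v * len(s) for v, s in zip(per_seq, seqs)], axis=0
            )
            return counts / counts.sum()
    else:
        raise ValueError(f"unknown composition kind {kind!r}")
    return np.mean(per_seq, axis=0)


def composition_series(values: np.ndarray) -> pd.Series:
    """Label a 400- or 20-vector with pair/residue names for export.

    The resulting Series writes directly to the two-column TSV layout used
    throughout the package (``pair<TAB>value`` / ``residue<TAB>value``).
    """
    values = np.asarray(values, dtype=float)
    if values.shape == (N_PAIRS,):
        index = pd.Index(DIPEPTIDES, name="pair")
    elif values.shape == (N_AA,):
        index = pd.Index(list(AMINO_ACIDS), name="residue")
    else:
        raise ValueError(f"expected a 20- or 400-vector, got shape {values.shape}")
    return pd.Series(values, index=index, name="value")
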