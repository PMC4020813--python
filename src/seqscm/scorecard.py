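"""Scoring cards: construction, sequence scoring, thresholding, serialization.

A scoring card assigns each of the 400 ordered dipeptides a propensity
score in [0, 1000] expressing how over-represented the pair is in the
positive class. The initial card is the min–max normalized difference of
the class mean dipeptide compositions. A sequence is scored by the
composition-weighted mean of its dipeptide scores,

    S(P) = sum_i w_i * s_i,

with w the sequence's 400 composition fractions (summing to one), so S(P)
always lies between the smallest and largest card score. Classification is
"positive iff S(P) > threshold" — strictly greater, equality is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .alphabet import DIPEPTIDES, N_AA, N_PAIRS, PAIR_INDEX
from .errors import CardError, EvaluationError
from .features import composition_matrix, dipeptide_composition
from .seqio import ProteinSequence

__all__ = [
    "ScoringCard",
    "initial_card",
    "derive_aa_scores",
    "score_sequence",
    "score_sequences",
    "choose_threshold",
    "classify",
    "save_card",
    "load_card",
]

SCORE_MIN = 0.0
SCORE_MAX = 1000.0

# (20, 400) averaging operator: row O sums the 40 scores of pairs OX and XO
# (the homo-dipeptide OO appears in both lists, so it is counted twice) and
# divides by 40.
_AA_FROM_PAIRS = np.zeros((N_AA, N_PAIRS))
for _o in range(N_AA):
    for _x in range(N_AA):
        _AA_FROM_PAIRS[_o, _o * N_AA + _x] += 1.0
        _AA_FROM_PAIRS[_o, _x * N_AA + _o] += 1.0
_AA_FROM_PAIRS /= 2 * N_AA


def derive_aa_scores(dipeptide_scores: np.ndarray) -> np.ndarray:
    """Per-residue scores: mean of the 40 dipeptide scores OX and XO.

    The homo-dipeptide (O, O) contributes twice; the divisor is 40.
    """
    scores = np.asarray(dipeptide_scores, dtype=float)
    if scores.shape != (N_PAIRS,):
        raise CardError(f"expected 400 dipeptide scores, got shape {scores.shape}")
    return _AA_FROM_PAIRS @ scores


@dataclass
class ScoringCard:
    """400 dipeptide propensity scores plus an optional decision threshold.

    ``aa_scores`` is always derived from the current dipeptide scores, never
    stored independently, so the two can not drift apart.
    """

    dipeptide_scores: np.ndarray
    threshold: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = np.asarray(self.dipeptide_scores, dtype=float)
        if scores.shape != (N_PAIRS,):
            raise CardError(
                f"expected 400 dipeptide scores, got shape {scores.shape}"
            )
        if not np.all(np.isfinite(scores)):
            raise CardError("dipeptide scores must be finite")
        if scores.min() < SCORE_MIN - 1e-9 or scores.max() > SCORE_MAX + 1e-9:
            raise CardError(
                f"dipeptide scores outside [0, 1000]: "
                f"min={scores.min():g}, max={scores.max():g}"
            )
        self.dipeptide_scores = scores

    @property
    def aa_scores(self) -> np.ndarray:
        """20 amino-acid scores derived from the dipeptide scores."""
        return derive_aa_scores(self.dipeptide_scores)

    def score(self, pair: str) -> float:
        """Score of a single dipeptide, e.g. ``card.score("GC")``."""
        try:
            return float(self.dipeptide_scores[PAIR_INDEX[pair]])
        except KeyError:
            raise CardError(f"unknown dipeptide {pair!r}") from None

    def with_scores(self, scores: np.ndarray, **metadata: Any) -> "ScoringCard":
        """New card with replaced scores; threshold is cleared (stale)."""
        meta = {**self.metadata, **metadata}
        return ScoringCard(dipeptide_scores=scores, threshold=None, metadata=meta)


def initial_card(
    pos_comp: np.ndarray,
    neg_comp: np.ndarray,
    metadata: dict[str, Any] | None = None,
) -> ScoringCard:
    """Initial card from class mean dipeptide compositions.

    Raw score of pair i is ``pos_i - neg_i``; the 400 differences are
    mapped affinely onto [0, 1000] (min -> 0, max -> 1000). If every
    difference is equal the map is degenerate and all scores are set
    to the mid-scale value 500.
    """
    pos = np.asarray(pos_comp, dtype=float)
    neg = np.asarray(neg_comp, dtype=float)
    if pos.shape != (N_PAIRS,) or neg.shape != (N_PAIRS,):
        raise CardError("compositions must be 400-vectors")
    diff = pos - neg
    span = diff.max() - diff.min()
    if span == 0.0:
        scores = np.full(N_PAIRS, 500.0)
    else:
        scores = SCORE_MAX * (diff - diff.min()) / span
        # pin the endpoints exactly despite floating-point rounding
        np.clip(scores, SCORE_MIN, SCORE_MAX, out=scores)
        scores[np.argmin(diff)] = SCORE_MIN
        scores[np.argmax(diff)] = SCORE_MAX
    return ScoringCard(
        dipeptide_scores=scores,
        threshold=None,
        metadata={"origin": "initial", **(metadata or {})},
    )


def score_sequence(seq: ProteinSequence, card: ScoringCard) -> float:
    """Weighted-sum sequence score S(P) in [min s_i, max s_i]."""
    w = dipeptide_composition(seq)
    return float(w @ card.dipeptide_scores)


def score_sequences(
    seqs: list[ProteinSequence], card: ScoringCard
) -> np.ndarray:
    """Vectorized :func:`score_sequence` over a list of sequences."""
    if not seqs:
        return np.empty(0)
    return composition_matrix(seqs) @ card.dipeptide_scores


def choose_threshold(
    pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[float, float]:
    """Threshold maximizing training accuracy of "positive iff S > t".

    Candidates are the midpoints between adjacent distinct values of the
    pooled sorted scores, plus one candidate below the minimum and one
    above the maximum (accuracy is piecewise constant between observed
    scores, so these candidates realize every achievable confusion table).
    Ties are broken toward the smallest qualifying threshold, which favors
    sensitivity.

    Returns
    -------
    (threshold, accuracy) : tuple of float
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("both score lists must be non-empty")
    distinct = np.unique(np.concatenate([pos, neg]))
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0,
         [distinct[-1] + 1.0]]
    )
    n = pos.size + neg.size
    # accuracy(t) = (#pos > t + #neg <= t) / n, vectorized over candidates
    tp = (pos[None, :] > candidates[:, None]).sum(axis=1)
    tn = (neg[None, :] <= candidates[:, None]).sum(axis=1)
    acc = (tp + tn) / n
    best = int(np.argmax(acc))  # argmax takes the first (smallest) maximizer
    return float(candidates[best]), float(acc[best])


def classify(
    seq: ProteinSequence, card: ScoringCard
) -> tuple[bool, float]:
    """Label a sequence with the card's threshold.

    Returns ``(is_positive, score)``; positive iff the score strictly
    exceeds the threshold.
    """
    if card.threshold is None:
        raise CardError("card has no threshold; train or set one first")
    s = score_sequence(seq, card)
    return s > card.threshold, s


# ---------------------------------------------------------------------------
# serialization: TSV of 400 (pair, score) rows with '#'-prefixed header lines

def save_card(card: ScoringCard, path: str | Path, *, round_to: int | None = None) -> None:
    """Write a card to TSV: header lines ``# key: value``, then 400 rows.

    Scores are written at full precision by default (lossless round-trip);
    ``round_to`` rounds for presentation-style exports.
    """
    path = Path(path)
    lines = []
    if card.threshold is not None:
        lines.append(f"# threshold: {card.threshold!r}")
    for key, value in sorted(card.metadata.items()):
        lines.append(f"# {key}: {value}")
    for pair, score in zip(DIPEPTIDES, card.dipeptide_scores):
        text = f"{score:.{round_to}f}" if round_to is not None else repr(float(score))
        lines.append(f"{pair}\t{text}")
    path.write_text("\n".join(lines) + "\n")


def load_card(path: str | Path) -> ScoringCard:
    """Read a card written by :func:`save_card`; strict about completeness."""
    path = Path(path)
    try:
        raw_lines = path.read_text().splitlines()
    except OSError as exc:
        raise CardError(f"cannot read card file {path}: {exc}") from exc

    threshold: float | None = None
    metadata: dict[str, Any] = {}
    scores = np.full(N_PAIRS, np.nan)
    for lineno, line in enumerate(raw_lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            key = key.strip()
            value = value.strip()
            if key == "threshold":
                threshold = float(value)
            elif key:
                metadata[key] = value
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[0] not in PAIR_INDEX:
            raise CardError(f"{path}:{lineno}: malformed row {line!r}")
        try:
            value = float(parts[1])
        except ValueError:
            raise CardError(f"{path}:{lineno}: non-numeric score {parts[1]!r}") from None
        if not SCORE_MIN <= value <= SCORE_MAX:
            raise CardError(
                f"{path}:{lineno}: score {value:g} for pair {parts[0]} "
                "outside [0, 1000]"
            )
        scores[PAIR_INDEX[parts[0]]] = value

    missing = np.isnan(scores)
    if missing.any():
        first = DIPEPTIDES[int(np.argmax(missing))]
        raise CardError(f"{path}: missing dipeptide {first}")
    return ScoringCard(dipeptide_scores=scores, threshold=threshold, metadata=metadata)
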