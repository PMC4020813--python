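"""Propensity-score analysis: property correlations, composition reports,
positional score profiles, histograms, heat-map export.

The amino-acid scores of a trained card are a 20-vector; correlating it
against per-residue physicochemical scales (AAindex-style 20-vectors)
identifies properties that the positive class is enriched or depleted in.
Correlations with zero-variance inputs are undefined and are reported as
missing, never coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AMINO_ACIDS, N_AA
from .errors import AnalysisError
from .features import class_mean_composition
from .scorecard import ScoringCard
from .seqio import ProteinSequence

__all__ = [
    "pearson",
    "PropertyTable",
    "property_scan",
    "composition_report",
    "mean_abs_difference",
    "positional_profile",
    "score_histogram",
    "card_heatmap_matrix",
]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises :class:`AnalysisError` on length < 2, length mismatch, or a
    zero-variance argument (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise AnalysisError(
            f"pearson needs two equal-length 1-d vectors of size >= 2, "
            f"got shapes {x.shape} and {y.shape}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("pearson undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class PropertyTable:
    """Named per-residue numeric scales (one column per property).

    Wraps a DataFrame indexed by the 20 one-letter residue codes in
    alphabetical order; every column must hold 20 finite values.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame
        if list(frame.index) != list(AMINO_ACIDS):
            try:
                frame = frame.loc[list(AMINO_ACIDS)]
            except KeyError as exc:
                raise AnalysisError(
                    "property table must have exactly the 20 standard "
                    f"residues as its index: {exc}"
                ) from exc
        if frame.shape[1] == 0:
            raise AnalysisError("property table has no property columns")
        if not np.isfinite(frame.to_numpy(dtype=float)).all():
            raise AnalysisError("property table contains non-finite values")
        self.frame = frame

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        """Read a ``residue<TAB>name1<TAB>name2...`` TSV (20 data rows)."""
        return cls(pd.read_csv(path, sep="\t", comment="#", index_col="residue"))

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)


def property_scan(aa_scores: np.ndarray, table: PropertyTable) -> pd.DataFrame:
    """Correlate amino-acid scores against every property in a table.

    Returns a DataFrame with columns ``property``, ``r`` and ``rank``
    (1 = largest \\|r\\|), sorted by \\|r\\| descending, ties broken by
    property name. Zero-variance properties appear with ``r`` = NaN and
    no rank.
    """
    aa_scores = np.asarray(aa_scores, dtype=float)
    rows = []
    for name in table.names:
        values = table.frame[name].to_numpy(dtype=float)
        try:
            r = pearson(aa_scores, values)
        except AnalysisError:
            r = np.nan
        rows.append({"property": name, "r": r})
    report = pd.DataFrame(rows)
    report["abs_r"] = report["r"].abs()
    report = report.sort_values(
        ["abs_r", "property"], ascending=[False, True], na_position="last"
    ).drop(columns="abs_r").reset_index(drop=True)
    defined = report["r"].notna()
    report["rank"] = np.where(defined, defined.cumsum(), np.nan)
    return report


def mean_abs_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute entry-wise difference of two composition vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AnalysisError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def composition_report(
    pos: list[ProteinSequence],
    neg: list[ProteinSequence],
    card: ScoringCard,
    *,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-residue table of card scores and class compositions (percent).

    Columns: ``score``, ``rank`` (1 = highest score), ``comp_pos``,
    ``comp_neg`` and ``diff`` (= comp_pos − comp_neg), residues
    alphabetical. Summary correlations between the score column and each
    composition column are attached in ``DataFrame.attrs["r"]``
    (NaN where undefined).
    """
    aa = card.aa_scores
    comp_pos = class_mean_composition(pos, "amino-acid", pooled=pooled) * 100.0
    comp_neg = class_mean_composition(neg, "amino-acid", pooled=pooled) * 100.0
    report = pd.DataFrame(
        {
            "score": aa,
            "rank": stats.rankdata(-aa, method="min").astype(int),
            "comp_pos": comp_pos,
            "comp_neg": comp_neg,
            "diff": comp_pos - comp_neg,
        },
        index=pd.Index(list(AMINO_ACIDS), name="residue"),
    )
    summary = {}
    for column in ("comp_pos", "comp_neg", "diff"):
        try:
            summary[column] = pearson(aa, report[column].to_numpy())
        except AnalysisError:
            summary[column] = float("nan")
    report.attrs["r"] = summary
    return report


def positional_profile(
    seq: ProteinSequence, card: ScoringCard, window: int = 1
) -> np.ndarray:
    """Dipeptide-score track along a sequence.

    Entry ``i`` of the raw track is the card score of the dipeptide
    starting at position ``i`` (L−1 values). ``window`` > 1 applies a
    centered moving average with truncated edges; it must be odd.
    """
    if window < 1 or window % 2 == 0:
        raise AnalysisError(f"window must be an odd integer >= 1, got {window}")
    from .features import dipeptide_composition  # validates length >= 2
    dipeptide_composition(seq)
    from .alphabet import encode

    codes = encode(seq.residues)
    track = card.dipeptide_scores[codes[:-1] * N_AA + codes[1:]]
    if window == 1:
        return track
    half = window // 2
    return np.array(
        [
            track[max(0, i - half): i + half + 1].mean()
            for i in range(track.size)
        ]
    )


def score_histogram(scores: np.ndarray, bin_width: float) -> pd.DataFrame:
    """Histogram of sequence scores over half-open bins covering [0, 1000].

    Returns a DataFrame with columns ``lo``, ``hi``, ``count``; bins are
    ``[lo, lo + width)`` and the counts sum to the number of scores. The
    last bin is extended to include scores equal to the upper edge 1000.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise AnalysisError("empty score list")
    if bin_width <= 0:
        raise AnalysisError(f"bin width must be positive, got {bin_width}")
    edges = np.arange(0.0, 1000.0 + bin_width, bin_width)
    if edges[-1] < 1000.0:
        edges = np.append(edges, edges[-1] + bin_width)
    idx = np.minimum(
        np.floor(scores / bin_width).astype(int), edges.size - 2
    )
    counts = np.bincount(idx, minlength=edges.size - 1)
    return pd.DataFrame({"lo": edges[:-1], "hi": edges[1:], "count": counts})


def card_heatmap_matrix(card: ScoringCard) -> pd.DataFrame:
    """Card scores as a 20x20 matrix: rows = first residue, cols = second."""
    matrix = card.dipeptide_scores.reshape(N_AA, N_AA)
    labels = pd.Index(list(AMINO_ACIDS))
    return pd.DataFrame(
        matrix, index=labels.rename("first"), columns=labels.rename("second")
    )
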