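"""ROC/AUC, stratified k-fold cross-validation and confusion-matrix metrics.

AUC uses the exact Mann–Whitney formulation — the fraction of
(positive, negative) score pairs in which the positive outscores the
negative, ties counted one half — computed in O(n log n) via midranks,
not by trapezoidal ROC integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigError, EvaluationError
from .scorecard import choose_threshold, initial_card
from .seqio import LabeledDataset

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .optimize import GAConfig

__all__ = ["EvalReport", "auc", "stratified_folds", "confusion_metrics", "cross_validate"]


def auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Area under the ROC curve by the Mann–Whitney pair-counting rule."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("AUC needs non-empty positive and negative scores")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def stratified_folds(
    data: LabeledDataset, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition each class into k near-equal parts (sizes differ by <= 1).

    Returns a list of k ``(pos_idx, neg_idx)`` held-out index pairs into
    ``data.positives`` / ``data.negatives``. Reproducible from ``seed``.
    """
    if not 2 <= k <= min(data.n_pos, data.n_neg):
        raise ConfigError(
            f"k={k} out of range [2, {min(data.n_pos, data.n_neg)}] "
            f"for dataset with {data.n_pos}+{data.n_neg} sequences"
        )
    rng = np.random.default_rng(seed)
    pos_parts = np.array_split(rng.permutation(data.n_pos), k)
    neg_parts = np.array_split(rng.permutation(data.n_neg), k)
    return [(np.sort(p), np.sort(n)) for p, n in zip(pos_parts, neg_parts)]


@dataclass
class EvalReport:
    """Classification metrics, overall and per fold.

    ``sensitivity``/``specificity`` are None when their denominator is
    zero (never silently coerced to 0). Percent formatting is left to
    presentation; all stored values are fractions in [0, 1].
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    per_fold: list["EvalReport"] = field(default_factory=list)
    protocol: str = ""

    def aggregate_sd(self, metric: str) -> float | None:
        """Sample s.d. of a metric over folds (None without folds)."""
        values = [getattr(f, metric) for f in self.per_fold]
        values = [v for v in values if v is not None]
        if len(values) < 2:
            return None
        return float(np.std(values, ddof=1))


def confusion_metrics(
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    threshold: float,
    *,
    protocol: str = "",
) -> EvalReport:
    """Metrics of the rule "positive iff score > threshold"."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    tp = int((pos > threshold).sum())
    fn = pos.size - tp
    tn = int((neg <= threshold).sum())
    fp = neg.size - tn
    total = tp + tn + fp + fn
    if total == 0:
        raise EvaluationError("no scores to evaluate")
    return EvalReport(
        accuracy=(tp + tn) / total,
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
        auc=auc(pos, neg) if pos.size and neg.size else None,
        tp=tp, tn=tn, fp=fp, fn=fn,
        protocol=protocol,
    )


def cross_validate(
    data: LabeledDataset,
    k: int,
    config: "GAConfig | None" = None,
    seed: int = 0,
    *,
    optimize: bool = True,
) -> EvalReport:
    """k-fold cross-validation with per-fold card training.

    For each fold: build the initial card from the k−1 training parts,
    optionally refine it with the genetic algorithm (``optimize=True``),
    choose the threshold on the training part, and evaluate on the
    held-out part. The aggregate report pools the per-fold confusion
    counts; per-fold metrics are attached for mean ± sd summaries.
    """
    from .features import composition_matrix
    from .optimize import GAConfig, ga_optimize

    if config is None:
        config = GAConfig()
    folds = stratified_folds(data, k, seed)
    w_pos = composition_matrix(data.positives)
    w_neg = composition_matrix(data.negatives)

    per_fold: list[EvalReport] = []
    tp = tn = fp = fn = 0
    protocol = "per-fold refit (initial card + GA)" if optimize else "per-fold initial card"
    for i, (test_pos, test_neg) in enumerate(folds):
        train_pos = np.setdiff1d(np.arange(data.n_pos), test_pos)
        train_neg = np.setdiff1d(np.arange(data.n_neg), test_neg)
        card = initial_card(
            w_pos[train_pos].mean(axis=0), w_neg[train_neg].mean(axis=0)
        )
        if optimize:
            fold_data = LabeledDataset(
                positives=[data.positives[j] for j in train_pos],
                negatives=[data.negatives[j] for j in train_neg],
                name=f"{data.name}/fold{i}",
            )
            fold_config = config.replace(seed=config.seed + i)
            card, _ = ga_optimize(card, fold_data, fold_config)
        else:
            thr, _ = choose_threshold(
                w_pos[train_pos] @ card.dipeptide_scores,
                w_neg[train_neg] @ card.dipeptide_scores,
            )
            card.threshold = thr
        report = confusion_metrics(
            w_pos[test_pos] @ card.dipeptide_scores,
            w_neg[test_neg] @ card.dipeptide_scores,
            card.threshold,
            protocol=f"fold {i}",
        )
        per_fold.append(report)
        tp += report.tp; tn += report.tn; fp += report.fp; fn += report.fn

    total = tp + tn + fp + fn
    fold_aucs = [f.auc for f in per_fold if f.auc is not None]
    return EvalReport(
        accuracy=(tp + tn) / total,
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
        auc=float(np.mean(fold_aucs)) if fold_aucs else None,
        tp=tp, tn=tn, fp=fp, fn=fn,
        per_fold=per_fold,
        protocol=protocol,
    )
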