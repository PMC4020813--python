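"""Model/Results facade over the scoring-card workflow.

``ScoringCardModel`` holds a labeled two-class training dataset and its
precomputed composition features; ``fit()`` builds the initial card,
refines it with the genetic algorithm, chooses the decision threshold,
and returns a ``ScoringCardResults`` carrying the card, the fitness
decomposition, training metrics and prediction/analysis helpers.

Example
-------
>>> from seqscm import ScoringCardModel, synthetic
>>> data = synthetic.generate(synthetic.benchmark_spec(seed=0))
>>> model = ScoringCardModel(data)
>>> results = model.fit()                      # doctest: +SKIP
>>> print(results.summary())                   # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import EvalReport, confusion_metrics, cross_validate
from .features import composition_matrix
from .optimize import FitnessReport, GAConfig, fitness, ga_optimize
from .scorecard import ScoringCard, initial_card, save_card, score_sequences
from .seqio import LabeledDataset, ProteinSequence, load_dataset

__all__ = ["ScoringCardModel", "ScoringCardResults"]


class ScoringCardModel:
    """Scoring-card classifier bound to a training dataset."""

    def __init__(self, data: LabeledDataset):
        self.data = data
        self._w_pos = composition_matrix(data.positives)
        self._w_neg = composition_matrix(data.negatives)

    @classmethod
    def from_fasta(
        cls, pos_path, neg_path, *, name: str = "", strict: bool = False
    ) -> "ScoringCardModel":
        """Build a model from two FASTA files (positives, negatives)."""
        return cls(load_dataset(pos_path, neg_path, name=name, strict=strict))

    def initial_card(self) -> ScoringCard:
        """Initial card: normalized class composition difference."""
        card = initial_card(
            self._w_pos.mean(axis=0),
            self._w_neg.mean(axis=0),
            metadata={"training_set": self.data.name},
        )
        return card

    def fit(self, config: GAConfig | None = None) -> "ScoringCardResults":
        """Train: initial card, GA refinement, threshold selection."""
        config = config or GAConfig()
        init = self.initial_card()
        card, report = ga_optimize(init, self.data, config)
        return ScoringCardResults(self, card, init, report, config)

    def fit_initial(self) -> "ScoringCardResults":
        """Skip the GA: initial card with a threshold (0 generations)."""
        return self.fit(GAConfig(generations=0))

    def cross_validate(
        self, k: int = 10, config: GAConfig | None = None, seed: int = 0,
        *, optimize: bool = True,
    ) -> EvalReport:
        """k-fold cross-validation with per-fold card training."""
        return cross_validate(self.data, k, config, seed, optimize=optimize)


class ScoringCardResults:
    """Fitted scoring card with its training diagnostics."""

    def __init__(
        self,
        model: ScoringCardModel,
        card: ScoringCard,
        init_card: ScoringCard,
        fitness_report: FitnessReport,
        config: GAConfig,
    ):
        self.model = model
        self.card = card
        self.init_card = init_card
        self.fitness_report = fitness_report
        self.config = config

    @property
    def threshold(self) -> float:
        return self.card.threshold

    @property
    def aa_scores(self) -> pd.Series:
        from .alphabet import AMINO_ACIDS

        return pd.Series(
            self.card.aa_scores,
            index=pd.Index(list(AMINO_ACIDS), name="residue"),
            name="score",
        )

    def training_report(self) -> EvalReport:
        """Confusion metrics of the fitted card on its own training data."""
        return confusion_metrics(
            self.model._w_pos @ self.card.dipeptide_scores,
            self.model._w_neg @ self.card.dipeptide_scores,
            self.card.threshold,
            protocol="training (resubstitution)",
        )

    def predict(self, sequences: list[ProteinSequence]) -> pd.DataFrame:
        """Score and label sequences; columns ``id``, ``score``, ``label``."""
        scores = score_sequences(sequences, self.card)
        return pd.DataFrame(
            {
                "id": [s.id for s in sequences],
                "score": scores,
                "label": np.where(
                    scores > self.card.threshold, "positive", "negative"
                ),
            }
        )

    def evaluate(
        self, positives: list[ProteinSequence], negatives: list[ProteinSequence]
    ) -> EvalReport:
        """Confusion metrics of the fitted card on an external test set."""
        return confusion_metrics(
            score_sequences(positives, self.card),
            score_sequences(negatives, self.card),
            self.card.threshold,
            protocol="external test",
        )

    def save(self, path: str | Path, *, round_to: int | None = None) -> None:
        save_card(self.card, path, round_to=round_to)

    def summary(self) -> str:
        """Human-readable fit summary."""
        train = self.training_report()
        rep = self.fitness_report
        lines = [
            "Scoring card fit",
            "=" * 58,
            f"training set        {self.model.data.name or '(unnamed)'}"
            f"  ({self.model.data.n_pos} pos / {self.model.data.n_neg} neg)",
            f"optimizer           GA pop={self.config.population_size} "
            f"gen={self.config.generations} seed={self.config.seed}",
            f"fitness             {rep.fitness:.4f} "
            f"(AUC {rep.auc_component:.4f} x {self.config.w1} "
            f"+ R {rep.r_component:.4f} x {self.config.w2})",
            f"threshold           {self.card.threshold:.3f}",
            f"training accuracy   {train.accuracy:.4f}  "
            f"sens {train.sensitivity:.4f}  spec {train.specificity:.4f}",
            f"training AUC        {train.auc:.4f}",
            "-" * 58,
            "top amino-acid scores:",
        ]
        top = self.aa_scores.sort_values(ascending=False).head(5)
        for residue, score in top.items():
            lines.append(f"    {residue}  {score:8.3f}")
        return "\n".join(lines)
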