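"""Real-coded genetic algorithm refining the 400 dipeptide scores.

The search maximizes

    fitness = w1 * AUC + w2 * R,        w1 = 0.9, w2 = 0.1 by default,

where AUC is the mean held-out area under the ROC curve over stratified
cross-validation folds of the training set (the candidate card is fixed,
only the evaluation rotates through folds) and R is Pearson's correlation
between the 20 amino-acid scores of the candidate card and those of the
initial card. The R term anchors the optimized card to the composition
statistics it started from and is the method's only overfitting guard.

Chromosomes are the 400 real scores, box-constrained to [0, 1000]:
tournament selection (size 2), BLX-alpha blend crossover, per-gene
Gaussian mutation, clipping after every operator, elitism >= 1. The
initial population is the initial card plus Gaussian perturbations. All
randomness flows from the config seed, so a (seed, config, data) triple
fully determines the returned card.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ConfigError
from .evaluate import auc, stratified_folds
from .features import composition_matrix
from .scorecard import (
    SCORE_MAX,
    SCORE_MIN,
    ScoringCard,
    choose_threshold,
    derive_aa_scores,
)
from .seqio import LabeledDataset

__all__ = ["GAConfig", "FitnessReport", "fitness", "ga_optimize"]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the fitness function and the genetic algorithm.

    Attributes
    ----------
    w1, w2 : float
        Fitness weights on the AUC and correlation terms; must be
        non-negative and sum to one.
    population_size, generations : int
        Population size and number of generations.
    crossover_rate : float
        Probability that an offspring is produced by BLX-alpha blending
        of two tournament-selected parents (otherwise a parent is copied).
    mutation_rate : float
        Per-gene probability of Gaussian mutation.
    mutation_sigma : float
        Mutation step s.d. in score units (range is [0, 1000]).
    blx_alpha : float
        Blend-interval extension of the BLX crossover.
    init_sigma : float
        S.d. of the Gaussian perturbations seeding the initial population.
    elitism : int
        Number of best individuals copied unchanged each generation (>= 1
        makes the best-so-far fitness non-decreasing).
    cv_folds : int
        Folds of the internal AUC cross-validation.
    cv_mode : {"heldout", "train"}
        Score the AUC term on held-out folds (default) or on the whole
        training set.
    patience : int or None
        Optional early stopping: stop after this many generations without
        improvement of the best fitness (None disables).
    seed : int
        Seed for population initialization, operators and fold assignment.
    """

    w1: float = 0.9
    w2: float = 0.1
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    mutation_sigma: float = 50.0
    blx_alpha: float = 0.5
    init_sigma: float = 100.0
    elitism: int = 1
    cv_folds: int = 10
    cv_mode: str = "heldout"
    patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ConfigError(f"fitness weights must be >= 0 and sum to 1, got w1={self.w1}, w2={self.w2}")
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        if self.elitism < 1 or self.elitism > self.population_size:
            raise ConfigError("elitism must be in [1, population_size]")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.cv_mode not in ("heldout", "train"):
            raise ConfigError(f"unknown cv_mode {self.cv_mode!r}")

    def replace(self, **changes: Any) -> "GAConfig":
        return dataclasses.replace(self, **changes)

    def digest(self) -> str:
        """Short config fingerprint for card metadata."""
        items = dataclasses.asdict(self)
        return ",".join(f"{k}={v}" for k, v in sorted(items.items()))


@dataclass
class FitnessReport:
    """Decomposition of the fitness of a card, plus the search trace."""

    fitness: float
    auc_component: float
    r_component: float
    per_generation_best: list[float] = field(default_factory=list)
    n_evaluations: int = 0


class _FitnessEvaluator:
    """Precomputed composition matrices + fold layout for fast evaluation."""

    def __init__(self, data: LabeledDataset, init_aa: np.ndarray, config: GAConfig):
        if config.cv_folds > min(data.n_pos, data.n_neg):
            raise ConfigError(
                f"cv_folds={config.cv_folds} exceeds the smaller class "
                f"size {min(data.n_pos, data.n_neg)}"
            )
        self.config = config
        self.w_pos = composition_matrix(data.positives)
        self.w_neg = composition_matrix(data.negatives)
        self.init_aa = init_aa - init_aa.mean()
        self.init_aa_norm = float(np.linalg.norm(self.init_aa))
        self.folds = stratified_folds(data, config.cv_folds, config.seed)
        self.n_evaluations = 0

    def auc_component(self, genes: np.ndarray) -> float:
        pos_scores = self.w_pos @ genes
        neg_scores = self.w_neg @ genes
        if self.config.cv_mode == "train":
            return auc(pos_scores, neg_scores)
        return float(
            np.mean([auc(pos_scores[p], neg_scores[n]) for p, n in self.folds])
        )

    def r_component(self, genes: np.ndarray) -> float:
        aa = derive_aa_scores(genes)
        aa = aa - aa.mean()
        denom = np.linalg.norm(aa) * self.init_aa_norm
        if denom == 0.0:
            # degenerate (constant) candidate: no correlation credit
            return 0.0
        return float(aa @ self.init_aa / denom)

    def __call__(self, genes: np.ndarray) -> tuple[float, float, float]:
        self.n_evaluations += 1
        a = self.auc_component(genes)
        r = self.r_component(genes)
        return self.config.w1 * a + self.config.w2 * r, a, r


def fitness(
    card: ScoringCard,
    init_card: ScoringCard,
    data: LabeledDataset,
    config: GAConfig | None = None,
) -> FitnessReport:
    """Evaluate a card's fitness against a training dataset."""
    config = config or GAConfig()
    evaluator = _FitnessEvaluator(data, init_card.aa_scores, config)
    f, a, r = evaluator(card.dipeptide_scores)
    return FitnessReport(fitness=f, auc_component=a, r_component=r, n_evaluations=1)


def ga_optimize(
    init_card: ScoringCard,
    data: LabeledDataset,
    config: GAConfig | None = None,
) -> tuple[ScoringCard, FitnessReport]:
    """Refine an initial card by the genetic algorithm.

    Returns the best card ever evaluated (elitism guarantees the trace of
    best fitness is non-decreasing and the result is at least as fit as
    the initial card) with its threshold re-chosen on the full training
    data, together with the fitness report and per-generation trace.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    evaluator = _FitnessEvaluator(data, init_card.aa_scores, config)
    n_genes = init_card.dipeptide_scores.size
    pop_size = config.population_size

    if config.generations == 0:
        # no search: return the initial card with a refreshed threshold
        f, a, r = evaluator(init_card.dipeptide_scores)
        card = ScoringCard(
            dipeptide_scores=init_card.dipeptide_scores.copy(),
            metadata={**init_card.metadata, "optimizer": "none (0 generations)"},
        )
        thr, _ = choose_threshold(
            evaluator.w_pos @ card.dipeptide_scores,
            evaluator.w_neg @ card.dipeptide_scores,
        )
        card.threshold = thr
        return card, FitnessReport(
            fitness=f, auc_component=a, r_component=r,
            per_generation_best=[f], n_evaluations=1,
        )

    population = np.clip(
        init_card.dipeptide_scores
        + rng.normal(0.0, config.init_sigma, size=(pop_size, n_genes)),
        SCORE_MIN, SCORE_MAX,
    )
    population[0] = init_card.dipeptide_scores  # keep the unperturbed card

    def evaluate_all(pop: np.ndarray) -> np.ndarray:
        return np.array([evaluator(ind)[0] for ind in pop])

    fits = evaluate_all(population)
    best_idx = int(np.argmax(fits))
    best_genes = population[best_idx].copy()
    best_fit = float(fits[best_idx])
    trace = [best_fit]
    stall = 0

    for _ in range(config.generations):
        order = np.argsort(fits)[::-1]
        elite = population[order[: config.elitism]].copy()

        n_children = pop_size - config.elitism
        children = np.empty((n_children, n_genes))
        for c in range(n_children):
            # tournament selection, size 2
            i, j = rng.integers(pop_size, size=2)
            p1 = population[i] if fits[i] >= fits[j] else population[j]
            if rng.random() < config.crossover_rate:
                i, j = rng.integers(pop_size, size=2)
                p2 = population[i] if fits[i] >= fits[j] else population[j]
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                span = (hi - lo) * config.blx_alpha
                children[c] = rng.uniform(lo - span, hi + span)
            else:
                children[c] = p1
        mutate = rng.random(children.shape) < config.mutation_rate
        children += mutate * rng.normal(0.0, config.mutation_sigma, children.shape)
        np.clip(children, SCORE_MIN, SCORE_MAX, out=children)

        population = np.vstack([elite, children])
        fits = np.concatenate([fits[order[: config.elitism]], evaluate_all(children)])

        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_genes = population[gen_best].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_fit)
        if config.patience is not None and stall >= config.patience:
            break

    _, auc_comp, r_comp = evaluator(best_genes)
    card = ScoringCard(
        dipeptide_scores=best_genes,
        metadata={
            **init_card.metadata,
            "origin": "ga-optimized",
            "optimizer": config.digest(),
            "seed": config.seed,
            "cv_mode": config.cv_mode,
        },
    )
    thr, _ = choose_threshold(
        evaluator.w_pos @ best_genes, evaluator.w_neg @ best_genes
    )
    card.threshold = thr
    report = FitnessReport(
        fitness=best_fit,
        auc_component=auc_comp,
        r_component=r_comp,
        per_generation_best=trace,
        n_evaluations=evaluator.n_evaluations,
    )
    return card, report
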