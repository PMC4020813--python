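# Methods

## Model

The scoring card method is a linear classifier on the 400-dimensional
simplex of ordered dipeptide compositions. A card assigns each ordered
pair *i* a propensity score *s<sub>i</sub>* ∈ [0, 1000]; a sequence of
length *L* contributes composition weights
*w<sub>i</sub>* = (count of adjacent windows equal to pair *i*) / (*L* − 1),
and its score is the weighted mean *S(P)* = Σ *w<sub>i</sub>s<sub>i</sub>*,
necessarily inside [min *s*, max *s*] ⊆ [0, 1000]. Classification is
"positive iff *S(P)* > threshold"; equality is negative because the
decision rule is a strict inequality.

Underlying assumptions: the discriminating signal is carried by
first-order adjacent-pair composition (no positional information, no
longer-range structure); both classes are exchangeable samples; and a
single global threshold is adequate (scores are calibrated only relative
to one training run).

### Initial card

With class mean compositions p and q (per-sequence vectors averaged with
equal weight, so a long sequence does not dominate), the raw score is
d<sub>i</sub> = p<sub>i</sub> − q<sub>i</sub>, mapped affinely so that
min → 0 and max → 1000 exactly (the argmin/argmax entries are pinned to
the endpoints to keep the invariant despite floating-point rounding). If
all d<sub>i</sub> are equal the map is degenerate and every score is set
to the mid-scale 500. The map is invariant to a common positive scaling
of both compositions, so percent and fraction inputs give the same card.
Pooled residue counting (weighting sequences by length) is available as a
flag for sensitivity analysis; class-level tables elsewhere derived from
pooled totals may differ slightly from the equal-weight default.

### Amino-acid scores

Residue *O*'s score is the mean of the 40 dipeptide scores {*OX*} ∪
{*XO*}, *X* ranging over all 20 residues; the homo-dipeptide *OO* appears
in both lists and is deliberately counted twice (divisor 40). Amino-acid
scores are always recomputed from the current dipeptide scores, never
stored, so they cannot drift.

### Threshold

Training accuracy as a function of the threshold is piecewise constant
with breakpoints at observed scores, so the search scans the midpoints of
adjacent distinct pooled scores plus one candidate below the minimum and
one above the maximum — this candidate set realizes every achievable
confusion table. Ties are broken toward the smallest qualifying
threshold, which favors sensitivity.

### Genetic-algorithm refinement

The GA maximizes fitness = *w₁*·AUC + *w₂*·*R* (defaults 0.9/0.1) over
the box [0, 1000]⁴⁰⁰:

* **AUC term** — mean held-out AUC over `cv_folds` (default 10)
  stratified folds of the training set. The candidate card is fixed;
  only the evaluation rotates through folds, which keeps fitness
  deterministic within a run (fold assignment is fixed by the seed).
  A whole-training-set mode (`cv_mode="train"`) exists behind a flag;
  the chosen mode is recorded in card metadata.
* **R term** — Pearson correlation between the candidate's and the
  initial card's 20 amino-acid scores. This anchors the search to the
  composition statistics and is the method's only overfitting guard; no
  additional regularization is added. A degenerate constant candidate
  receives R = 0 (no credit) rather than an undefined value.

Operators: tournament selection of size 2; BLX-α crossover (α = 0.5)
applied with probability 0.9, otherwise the parent is copied; per-gene
Gaussian mutation (rate 0.05, σ = 50 score units); clipping to
[0, 1000] after every operator; elitism 1 (so the best-so-far trace is
non-decreasing and the returned best-ever card is at least as fit as the
initial card). The initial population is the unperturbed initial card
plus Gaussian perturbations (σ = 100). Defaults: population 50,
generations 100. Optional early stopping (`patience`) is off by default.
`generations=0` returns the initial card with only the threshold
refreshed. AUC itself is computed by the exact Mann–Whitney midrank
formulation (ties one half), not trapezoidal integration, so it is
oracle-checkable by direct pair counting.

All randomness — population init, operators, fold assignment — flows from
the config seed; a (seed, config, data) triple reproduces the card and
all score tables byte-for-byte.

### Cross-validation protocols

`cross_validate` re-derives the card per fold (initial card + GA on the
k−1 training parts, threshold on the training part, metrics on the
held-out part) — the honest protocol for generalization estimates. A
cheaper `optimize=False` mode builds only the per-fold initial card with
its threshold; reports label which protocol produced them. Sensitivity
and specificity with zero denominators are reported as missing, never as
zero.

## Analysis toolkit

Correlation scans pair the 20 amino-acid scores with per-residue
physicochemical scales (simple TSV: residue column plus one column per
property). Zero-variance vectors make the correlation undefined; such
rows are reported as missing and excluded from ranking, never coerced to
0. The package bundles the published reference tables for the two tasks
it was built around — bioluminescent proteins vs non-BLPs and luciferases
vs fluorescent proteins — comprising per-residue propensity scores, class
compositions, four AAindex-derived property scales and the compositions
of integral membrane and nuclear proteins. The acceptance script
recomputes all their correlation statistics (e.g. score vs composition
difference R ≈ 0.97 for the BLP card and 0.9996 for the luciferase card;
BLP vs membrane-protein composition R ≈ 0.921). Positional profiles are
the raw L−1 dipeptide-score track, with opt-in centered moving-average
smoothing (window odd, edges truncated; no smoothing by default since
there is no canonical window). Histograms use half-open bins covering
[0, 1000], the top edge inclusive.

## Synthetic data generator

The generator emulates the statistical structure of the real two-class
datasets — classes separable through mean dipeptide composition on a
known subset of pairs — not protein biology. Negatives are first-order
Markov chains with uniform initial distribution and uniform rows (1/20);
positives raise each planted pair (a, b) to transition probability
1/20 + δ in row a and renormalize the rest of that row. The signal is
planted exactly in the feature space the card measures, which makes
parameter recovery directly interpretable. What the generator does *not*
emulate: realistic residue frequencies, domain structure, length
distributions or phylogenetic correlation between sequences — so passing
tests validate the machinery, not any biological claim.

The repository's fixed benchmark is 200+200 sequences of length 200 with
10 planted pairs (distinct source rows) at δ = 0.015, seeds 0–4, plus a
δ = 0 null control. **Known limitation:** at δ = 0.015 the planted signal
is intrinsically weak. Each planted pair's expected composition rises
from 1/400 to 0.00325, about 2.1 standard deviations of the rank noise of
the initial card's score estimates, and the Bayes-optimal
likelihood-ratio classifier on this generator tops out near held-out AUC
0.67 (accuracy ≈ 0.62). The benchmark therefore measures *partial*
recovery: typically 6–8 of 10 planted pairs reach the initial card's top
20, and held-out 10-fold accuracy sits near 0.55, well below what a
stronger bias (δ ≳ 0.05) yields (essentially complete recovery; see the
unit tests). The null control behaves as designed: held-out AUC stays in
[0.40, 0.60]. The benchmark's parameters are fixed with the repository so
these numbers are reproducible, and the acceptance script reports them as
measured.

## Numerical choices

* Compositions sum to 1 (fractions) internally; percent is presentation
  only. Thresholds near ~440 on a [0, 1000] card are only meaningful
  with fraction weights.
* Card serialization is full-precision `repr` TSV (lossless round-trip);
  `round_to=3` gives presentation-style exports.
* Test-suite problem sizes: unit tests run the GA at population 8–10 for
  5–15 generations on datasets of 20–160 sequences, which is enough to
  exercise every contract; the acceptance tests and script use the full
  default configuration (population 50, 100 generations) on the fixed
  benchmark.
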