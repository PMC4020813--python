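"""Scoring cards: initialization, amino-acid scores, scoring, thresholds,
classification, serialization."""

import numpy as np
import pytest

from seqscm.alphabet import AMINO_ACIDS, DIPEPTIDES, PAIR_INDEX
from seqscm.errors import CardError, EvaluationError
from seqscm.features import dipeptide_composition
from seqscm.scorecard import (
    ScoringCard,
    choose_threshold,
    classify,
    derive_aa_scores,
    initial_card,
    load_card,
    save_card,
    score_sequence,
)

from conftest import make_seq, random_seq


def uniform_comp():
    return np.full(400, 1 / 400)


class TestInitialCard:
    def test_three_level_affine_map(self):
        pos, neg = uniform_comp(), uniform_comp()
        delta = 1e-3
        pos[PAIR_INDEX["AC"]] += delta
        pos[PAIR_INDEX["CA"]] -= delta
        card = initial_card(pos, neg)
        assert card.score("AC") == pytest.approx(1000.0)
        assert card.score("CA") == pytest.approx(0.0)
        others = np.delete(
            card.dipeptide_scores, [PAIR_INDEX["AC"], PAIR_INDEX["CA"]]
        )
        np.testing.assert_allclose(others, 500.0)

    def test_identical_compositions_degenerate_to_midscale(self):
        card = initial_card(uniform_comp(), uniform_comp())
        np.testing.assert_allclose(card.dipeptide_scores, 500.0)
        assert card.threshold is None

    def test_matches_affine_map_oracle(self, rng):
        pos = rng.dirichlet(np.ones(400))
        neg = rng.dirichlet(np.ones(400))
        card = initial_card(pos, neg)
        d = pos - neg
        expected = 1000 * (d - d.min()) / (d.max() - d.min())
        np.testing.assert_allclose(card.dipeptide_scores, expected)
        assert card.dipeptide_scores.min() == 0.0
        assert card.dipeptide_scores.max() == 1000.0

    def test_affine_invariance_under_common_scaling(self, rng):
        pos = rng.dirichlet(np.ones(400))
        neg = rng.dirichlet(np.ones(400))
        a = initial_card(pos, neg)
        b = initial_card(pos * 100, neg * 100)  # percent vs fraction
        np.testing.assert_allclose(a.dipeptide_scores, b.dipeptide_scores)


class TestAminoAcidScores:
    def test_constant_card(self):
        assert np.allclose(derive_aa_scores(np.full(400, 321.0)), 321.0)

    def test_single_nonzero_pair_spreads_1000_over_40(self):
        scores = np.zeros(400)
        scores[PAIR_INDEX["GC"]] = 1000.0
        aa = derive_aa_scores(scores)
        by_res = dict(zip(AMINO_ACIDS, aa))
        assert by_res["G"] == pytest.approx(25.0)
        assert by_res["C"] == pytest.approx(25.0)
        assert sum(v for r, v in by_res.items() if r not in "GC") == 0.0

    def test_matches_40_term_sum_oracle(self, rng):
        scores = rng.uniform(0, 1000, 400)
        aa = derive_aa_scores(scores)
        for i, o in enumerate(AMINO_ACIDS):
            terms = [scores[PAIR_INDEX[o + x]] for x in AMINO_ACIDS]
            terms += [scores[PAIR_INDEX[x + o]] for x in AMINO_ACIDS]
            assert len(terms) == 40  # homo-dipeptide counted twice
            assert aa[i] == pytest.approx(sum(terms) / 40)

    def test_uniform_random_card_scores_stay_in_range(self, rng):
        aa = derive_aa_scores(rng.uniform(0, 1000, 400))
        assert (aa >= 0).all() and (aa <= 1000).all()

    def test_card_property_tracks_mutation(self, rng):
        card = ScoringCard(dipeptide_scores=rng.uniform(0, 1000, 400))
        card2 = card.with_scores(np.full(400, 10.0))
        np.testing.assert_allclose(card2.aa_scores, 10.0)


class TestScoreSequence:
    def test_constant_card_gives_constant_score(self, rng):
        card = ScoringCard(dipeptide_scores=np.full(400, 500.0))
        assert score_sequence(random_seq(rng, 30), card) == pytest.approx(500.0)

    def test_two_term_weighted_sum(self):
        scores = np.full(400, 0.0)
        scores[PAIR_INDEX["AC"]] = 900.0
        scores[PAIR_INDEX["CA"]] = 300.0
        card = ScoringCard(dipeptide_scores=scores)
        # "ACAC": windows AC, CA, AC -> w(AC)=2/3, w(CA)=1/3
        assert score_sequence(make_seq("ACAC"), card) == pytest.approx(700.0)

    def test_matches_dot_product_oracle(self, rng):
        card = ScoringCard(dipeptide_scores=rng.uniform(0, 1000, 400))
        seq = random_seq(rng, 64)
        expected = float(dipeptide_composition(seq) @ card.dipeptide_scores)
        assert score_sequence(seq, card) == pytest.approx(expected)

    def test_score_bounded_by_card_extremes(self, rng):
        for _ in range(20):
            card = ScoringCard(dipeptide_scores=rng.uniform(0, 1000, 400))
            s = score_sequence(random_seq(rng, int(rng.integers(2, 50))), card)
            assert card.dipeptide_scores.min() - 1e-9 <= s
            assert s <= card.dipeptide_scores.max() + 1e-9

    def test_composition_equal_sequences_score_equal(self, rng):
        card = ScoringCard(dipeptide_scores=rng.uniform(0, 1000, 400))
        # same multiset of windows, different ids
        a = make_seq("ACAC", id="a")
        b = make_seq("CACA"[::-1], id="b")  # "ACAC" again under a new id
        assert score_sequence(a, card) == score_sequence(b, card)


class TestThreshold:
    def test_separable_midpoint(self):
        thr, acc = choose_threshold([700.0, 700.0], [300.0, 300.0])
        assert thr == pytest.approx(500.0)
        assert acc == 1.0

    def test_all_tied_returns_smallest_candidate(self):
        thr, acc = choose_threshold([400.0, 400.0], [400.0, 400.0])
        assert acc == pytest.approx(0.5)
        assert thr < 400.0  # the below-minimum candidate

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(20):
            pos = rng.uniform(0, 1000, 5)
            neg = rng.uniform(0, 1000, 5)
            thr, acc = choose_threshold(pos, neg)
            # brute force over a dense grid of candidate thresholds
            grid = np.union1d(
                np.concatenate([pos, neg]) - 1e-6,
                np.concatenate([pos, neg]) + 1e-6,
            )
            accs = [
                ((pos > t).sum() + (neg <= t).sum()) / 10 for t in grid
            ]
            assert acc == pytest.approx(max(accs))
            assert ((pos > thr).sum() + (neg <= thr).sum()) / 10 == pytest.approx(acc)

    def test_empty_input_rejected(self):
        with pytest.raises(EvaluationError):
            choose_threshold([], [1.0])


class TestClassify:
    def test_above_threshold_is_positive(self, rng):
        card = ScoringCard(
            dipeptide_scores=np.full(400, 600.0), threshold=439.63
        )
        label, score = classify(random_seq(rng, 20), card)
        assert label is True
        assert score == pytest.approx(600.0)

    def test_equality_is_negative(self, rng):
        card = ScoringCard(dipeptide_scores=np.full(400, 500.0), threshold=500.0)
        label, score = classify(random_seq(rng, 20), card)
        assert label is False
        assert score == pytest.approx(500.0)

    def test_unset_threshold_is_usage_error(self, rng):
        card = ScoringCard(dipeptide_scores=np.full(400, 500.0))
        with pytest.raises(CardError, match="threshold"):
            classify(random_seq(rng, 20), card)


class TestSerialization:
    def test_lossless_roundtrip(self, tmp_path, rng):
        card = ScoringCard(
            dipeptide_scores=rng.uniform(0, 1000, 400),
            threshold=439.627,
            metadata={"training_set": "demo"},
        )
        path = tmp_path / "card.tsv"
        save_card(card, path)
        loaded = load_card(path)
        np.testing.assert_array_equal(loaded.dipeptide_scores, card.dipeptide_scores)
        assert loaded.threshold == card.threshold
        assert loaded.metadata["training_set"] == "demo"

    def test_missing_pair_named(self, tmp_path, rng):
        card = ScoringCard(dipeptide_scores=rng.uniform(0, 1000, 400))
        path = tmp_path / "card.tsv"
        save_card(card, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("GC\t")]
        path.write_text("\n".join(lines))
        with pytest.raises(CardError, match="GC"):
            load_card(path)

    def test_out_of_range_score_rejected(self, tmp_path):
        path = tmp_path / "card.tsv"
        path.write_text(
            "\n".join(f"{p}\t500.0" for p in DIPEPTIDES[:-1]) + f"\n{DIPEPTIDES[-1]}\t1001.0\n"
        )
        with pytest.raises(CardError, match=r"\[0, 1000\]"):
            load_card(path)

    def test_rounded_export(self, tmp_path):
        card = ScoringCard(dipeptide_scores=np.full(400, 573.02512))
        path = tmp_path / "card.tsv"
        save_card(card, path, round_to=3)
        assert "573.025" in path.read_text()

    def test_constructor_rejects_bad_shapes_and_ranges(self):
        with pytest.raises(CardError):
            ScoringCard(dipeptide_scores=np.zeros(399))
        with pytest.raises(CardError):
            ScoringCard(dipeptide_scores=np.full(400, -1.0))
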