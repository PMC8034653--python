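"""Pseudo-energy restraints, the folding engines, relaxed comparison and
the slope/intercept grid search."""

import numpy as np
import pytest

from shapebench import (PseudoEnergyParams, ReactivityProfile,
                        ViennaRNAEngine, fold, grid_search, pseudo_energy,
                        relaxed_compare)
from shapebench.formats import ReferenceStructure
from shapebench.synthetic import sample_structure


class TestPseudoEnergy:
    def test_zero_reactivity_gives_intercept(self):
        out = pseudo_energy(np.array([0.0]), PseudoEnergyParams(m=1.7, b=-0.6))
        assert out[0] == pytest.approx(-0.6)

    def test_unit_reactivity_top_parameters(self):
        # the best-performing slope/intercept pair for a strong reagent
        out = pseudo_energy(np.array([1.0]), PseudoEnergyParams(m=1.0, b=-0.4))
        assert out[0] == pytest.approx(np.log(2) - 0.4)

    def test_zero_parameters_unconstrained(self):
        out = pseudo_energy(np.array([0.0, 0.5, 2.0]), PseudoEnergyParams(0.0, 0.0))
        np.testing.assert_allclose(out, 0.0)

    def test_missing_stays_missing_and_negative_rejected(self):
        out = pseudo_energy(np.array([np.nan, 1.0]), PseudoEnergyParams(1.0, 0.0))
        assert np.isnan(out[0])
        with pytest.raises(ValueError):
            pseudo_energy(np.array([-0.1]), PseudoEnergyParams(1.0, 0.0))


class TestFold:
    def test_deterministic_hairpin(self):
        a = fold("GGGGAAAACCCC")
        b = fold("GGGGAAAACCCC")
        assert a.dotbracket == b.dotbracket == "((((....))))"

    def test_max_pair_distance_honoured(self):
        for seed in range(5):
            s = sample_structure(120, seed)
            pred = fold(s.sequence, max_pair_distance=30)
            assert all(j - i <= 30 for i, j in pred.pairs())

    def test_no_lonely_pairs_by_default(self):
        for seed in range(5):
            s = sample_structure(100, seed + 50)
            pairs = set(fold(s.sequence).pairs())
            for i, j in pairs:
                assert (i + 1, j - 1) in pairs or (i - 1, j + 1) in pairs

    def test_zero_restraints_identical_to_unconstrained(self):
        for seed in range(5):
            s = sample_structure(80, seed)
            unconstrained = fold(s.sequence)
            zeroed = fold(s.sequence, np.zeros(s.n))
            assert unconstrained.pairs() == zeroed.pairs()

    def test_strong_penalty_removes_helix(self):
        s = sample_structure(80, 1)
        baseline = set(fold(s.sequence).pairs())
        i0, j0 = sorted(baseline)[0]
        penalties = np.zeros(s.n)
        # heavily penalise pairing of the first helix's opening strand
        for i, j in baseline:
            if abs(i - i0) <= 3:
                penalties[i - 1] = 50.0
        refolded = set(fold(s.sequence, penalties).pairs())
        assert all(penalties[i - 1] == 0 for i, j in refolded)

    def test_vienna_engine_adapter(self):
        pred = fold("GGGGAAAACCCC", engine=ViennaRNAEngine())
        assert pred.dotbracket == "((((....))))"
        # restraints steer the Vienna engine too
        pen = np.zeros(12)
        pen[:4] = 50.0
        pred2 = fold("GGGGAAAACCCC", pen, engine=ViennaRNAEngine())
        assert not pred2.pairs()


class TestRelaxedCompare:
    def test_identity_scores_one(self):
        s = sample_structure(60, 2)
        score = relaxed_compare(s, s)
        assert score.ppv == score.sensitivity == 1.0
        assert score.gmean == 1.0

    def test_one_off_pair_accepted(self):
        ref = ReferenceStructure.from_pairs("r", "A" * 40, [(10, 21)])
        pred = ReferenceStructure.from_pairs("p", "A" * 40, [(10, 20)])
        assert relaxed_compare(pred, ref).ppv == 1.0
        assert relaxed_compare(pred, ref, relaxed=False).ppv == 0.0

    def test_shifted_helix_relaxed_one_strict_zero(self):
        ref_pairs = [(10 + k, 30 - k) for k in range(5)]
        pred_pairs = [(10 + k, 29 - k) for k in range(5)]
        ref = ReferenceStructure.from_pairs("r", "A" * 40, ref_pairs)
        pred = ReferenceStructure.from_pairs("p", "A" * 40, pred_pairs)
        relaxed = relaxed_compare(pred, ref)
        strict = relaxed_compare(pred, ref, relaxed=False)
        assert relaxed.ppv == 1.0 and relaxed.sensitivity == 1.0
        assert strict.ppv == 0.0 and strict.sensitivity == 0.0

    def test_relaxed_dominates_strict(self):
        for seed in range(20):
            ref = sample_structure(60, seed)
            pred = sample_structure(60, seed + 1000)
            r = relaxed_compare(pred, ref)
            s = relaxed_compare(pred, ref, relaxed=False)
            assert r.ppv >= s.ppv and r.sensitivity >= s.sensitivity

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            relaxed_compare(sample_structure(60, 0), sample_structure(70, 0))

    def test_gmean_bounds(self):
        s = sample_structure(60, 5)
        pred = fold(s.sequence)
        score = relaxed_compare(pred, s)
        assert score.gmean <= max(score.ppv, score.sensitivity) + 1e-12
        assert (score.gmean == 0) == (score.ppv == 0 or score.sensitivity == 0)


class TestGridSearch:
    def _perfect_reactivity(self, s):
        return ReactivityProfile(s.id, np.where(s.pair_table[1:] == 0, 1.0, 0.0))

    def test_zero_only_grid_equals_unconstrained(self):
        s = sample_structure(80, 3)
        react = self._perfect_reactivity(s)
        grid = grid_search([(react, s)], m_grid=[0.0], b_grid=[0.0])
        pred = fold(s.sequence)
        expected = relaxed_compare(pred, s).gmean
        assert grid.best_score == pytest.approx(expected)
        assert grid.best_params == PseudoEnergyParams(0.0, 0.0)

    def test_perfect_reactivities_reach_at_least_unconstrained(self):
        s = sample_structure(100, 4)
        react = self._perfect_reactivity(s)
        grid = grid_search([(react, s)], m_grid=[0.0, 1.0, 2.0, 3.0],
                           b_grid=[0.0, -0.4, -0.8])
        zero_cell = grid.scores[0, 0]
        assert grid.best_score >= zero_cell

    def test_duplicate_rna_averaging_idempotent(self):
        s = sample_structure(80, 6)
        react = self._perfect_reactivity(s)
        one = grid_search([(react, s)], m_grid=[0.0, 1.0], b_grid=[0.0, -0.4])
        two = grid_search([(react, s), (react, s)], m_grid=[0.0, 1.0],
                          b_grid=[0.0, -0.4])
        np.testing.assert_allclose(one.scores, two.scores)

    def test_tie_break_prefers_small_magnitude(self):
        # a constant-zero reactivity makes every cell with b=0 score equally
        s = sample_structure(80, 7)
        react = ReactivityProfile(s.id, np.zeros(s.n))
        grid = grid_search([(react, s)], m_grid=[2.0, 0.0], b_grid=[0.0])
        assert grid.best_params.m == 0.0

    def test_empty_grid_errors(self):
        s = sample_structure(80, 8)
        with pytest.raises(ValueError):
            grid_search([(self._perfect_reactivity(s), s)], m_grid=[], b_grid=[0.0])
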