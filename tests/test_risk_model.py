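"""Frequency bins, group histograms, the lookup table and risk scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import icdrisk as ir
from icdrisk import risk_model as rm

from conftest import random_frequency_matrix


class TestBinIndex:
    @pytest.mark.parametrize(
        "f,j",
        [(1, 1), (2, 1), (3, 2), (5, 2), (6, 3), (10, 3), (11, 4), (20, 4),
         (21, 5), (1_000_000, 5)],
    )
    def test_bin_boundaries(self, f, j):
        assert ir.bin_index(f) == j

    def test_zero_count_has_no_bin(self):
        assert ir.bin_index(0) == 0

    @pytest.mark.parametrize("f", [-1, 2.5])
    def test_invalid_counts_rejected(self, f):
        with pytest.raises(ValueError):
            ir.bin_index(f)

    @given(st.integers(1, 10_000))
    def test_positive_integers_fall_in_exactly_one_bin(self, f):
        j = ir.bin_index(f)
        assert 1 <= j <= 5
        lo, hi = rm.BIN_BOUNDS[j - 1]
        assert lo <= f and (hi is None or f <= hi)

    def test_vectorized_bins_match_scalar(self):
        f = np.array([0, 1, 2, 3, 5, 6, 10, 11, 20, 21, 100])
        assert rm.bin_indices(f).tolist() == [ir.bin_index(x) for x in f]


def _matrix_from_chapter1(control_counts, risk_counts):
    """Single-window-relevant matrix: given chapter-1 counts per group."""
    counts = list(control_counts) + list(risk_counts)
    values = np.zeros((len(counts), 5, 18), dtype=int)
    values[:, :, 0] = np.array(counts)[:, None]  # same in every window
    labels = np.array([0] * len(control_counts) + [1] * len(risk_counts))
    return ir.FrequencyMatrix(
        values=values, assessment_ids=np.arange(len(counts)), labels=labels
    )


class TestHistograms:
    def test_hand_counted_rows(self):
        F = _matrix_from_chapter1([1, 2, 3, 0], [2, 5, 0, 0])
        control, risk = ir.build_histograms(F)
        assert control.counts[0, 0].tolist() == [2, 1, 0, 0, 0]
        assert risk.counts[0, 0].tolist() == [1, 1, 0, 0, 0]
        # zero frequencies contribute nowhere
        assert control.counts[0, 0].sum() == 3
        assert risk.counts[0, 0].sum() == 2

    def test_all_zero_chapter_gives_all_zero_rows(self):
        F = _matrix_from_chapter1([1, 0], [2, 0])
        control, risk = ir.build_histograms(F)
        assert control.counts[:, 1:, :].sum() == 0
        assert risk.counts[:, 1:, :].sum() == 0

    def test_single_group_training_rejected(self):
        F = _matrix_from_chapter1([1, 2], [])
        F.labels = np.zeros(2, dtype=int)
        with pytest.raises(ValueError, match="both control and risk"):
            ir.build_histograms(F)

    def test_conservation_against_nonzero_counts(self):
        """Sum over bins equals the count of group assessments with f != 0."""
        rng = np.random.default_rng(3)
        F = random_frequency_matrix(rng, 40)
        control, risk = ir.build_histograms(F)
        for hist, mask in ((control, F.labels == 0), (risk, F.labels == 1)):
            nonzero = (F.values[mask] != 0).sum(axis=0)
            np.testing.assert_array_equal(hist.counts.sum(axis=2), nonzero)


class TestLookup:
    def test_worked_normalized_ratio_example(self):
        """Control bins [2,1,0,0,0] (3 nonzero), risk [1,1,0,0,0] (2 nonzero):
        pt_1 = (1/2)/(1/2 + 2/3), pt_2 = (1/2)/(1/2 + 1/3)."""
        F = _matrix_from_chapter1([1, 2, 3, 0], [2, 5, 0, 0])
        table = ir.build_lookup(F)
        assert table.lookup(1, 1, 1) == pytest.approx(0.428571, abs=1e-6)
        assert table.lookup(1, 1, 2) == pytest.approx(0.6, abs=1e-12)

    def test_identical_groups_give_half_everywhere(self):
        F = _matrix_from_chapter1([1, 2, 5, 12], [1, 2, 5, 12])
        table = ir.build_lookup(F)
        defined = ~np.isnan(table.probabilities)
        assert np.allclose(table.probabilities[defined], 0.5)

    def test_risk_only_bin_gives_probability_one(self):
        F = _matrix_from_chapter1([1], [25])
        table = ir.build_lookup(F)
        assert table.lookup(1, 1, 5) == 1.0

    def test_raw_ratio_variant(self):
        F = _matrix_from_chapter1([1, 1, 1], [1])
        table = ir.build_lookup(F, variant="raw-ratio")
        assert table.lookup(1, 1, 1) == pytest.approx(0.25)
        assert table.variant == "raw-ratio"

    def test_empty_cells_are_undefined(self):
        F = _matrix_from_chapter1([1], [2])
        table = ir.build_lookup(F)
        assert np.isnan(table.lookup(1, 2, 1))  # chapter 2 never seen
        assert table.n_undefined > 0

    def test_probabilities_bounded(self, paper_like):
        F = paper_like["F"]
        table = ir.build_lookup(F)
        defined = ~np.isnan(table.probabilities)
        assert ((table.probabilities[defined] >= 0)
                & (table.probabilities[defined] <= 1)).all()

    def test_determinism(self):
        F = random_frequency_matrix(np.random.default_rng(5), 30)
        t1 = ir.build_lookup(F)
        t2 = ir.build_lookup(F)
        np.testing.assert_array_equal(t1.probabilities, t2.probabilities)

    def test_json_round_trip_lossless(self, tmp_path):
        F = _matrix_from_chapter1([1, 2, 3, 0], [2, 5, 0, 0])
        table = ir.build_lookup(F, theta=0.4)
        text = table.to_json()
        back = ir.LookupTable.from_json(text)
        np.testing.assert_array_equal(
            np.isnan(back.probabilities), np.isnan(table.probabilities)
        )
        defined = ~np.isnan(table.probabilities)
        np.testing.assert_array_equal(
            back.probabilities[defined], table.probabilities[defined]
        )
        assert back.theta == table.theta and back.variant == table.variant
        assert (back.n_control, back.n_risk) == (table.n_control, table.n_risk)


class TestHeaviside:
    @pytest.mark.parametrize(
        "p,theta,expected",
        [(0.6, 0.5, 1), (0.428571, 0.5, 0), (0.5, 0.5, 1), (np.nan, 0.5, 0)],
    )
    def test_threshold_and_tie_rule(self, p, theta, expected):
        assert ir.heaviside(p, theta) == expected

    @pytest.mark.parametrize("theta", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_theta_rejected(self, theta):
        with pytest.raises(ValueError):
            ir.heaviside(0.5, theta)


class TestScoring:
    def test_worked_single_window_example(self):
        """Chapter-1 count 5 falls in bin 2 where pt = 0.6 >= 0.5 -> score 1."""
        F = _matrix_from_chapter1([1, 2, 3, 0], [2, 5, 0, 0])
        table = ir.build_lookup(F)
        f_row = np.zeros((5, 18), dtype=int)
        f_row[0, 0] = 5
        score = ir.score_assessment(f_row, table, model=1, mode="binary")
        assert score.value == 1.0
        assert score.components == {(1, 1): 1.0}

    def test_all_zero_row_scores_zero(self):
        F = _matrix_from_chapter1([1, 2], [3, 4])
        table = ir.build_lookup(F)
        zeros = np.zeros((5, 18), dtype=int)
        for model in rm.MODELS:
            for mode in ("binary", "weighted"):
                assert ir.score_assessment(zeros, table, model, mode).value == 0.0

    def test_combined_score_sums_single_window_scores(self):
        rng = np.random.default_rng(8)
        F = random_frequency_matrix(rng, 25)
        table = ir.build_lookup(F)
        row = F.values[3]
        singles = sum(
            ir.score_assessment(row, table, model=t).value for t in range(1, 6)
        )
        combined = ir.score_assessment(row, table, model="combined").value
        assert combined == singles
        assert combined >= ir.score_assessment(row, table, model=2).value

    def test_score_equals_sum_of_components(self):
        rng = np.random.default_rng(9)
        F = random_frequency_matrix(rng, 20)
        table = ir.build_lookup(F)
        for i in range(5):
            for mode in ("binary", "weighted"):
                s = ir.score_assessment(F.values[i], table, "combined", mode)
                assert s.value == pytest.approx(sum(s.components.values()))

    def test_malformed_row_rejected(self):
        F = _matrix_from_chapter1([1], [2])
        table = ir.build_lookup(F)
        with pytest.raises(ValueError):
            ir.score_assessment(np.zeros((4, 18)), table)

    def test_vectorized_scores_match_scalar(self):
        rng = np.random.default_rng(10)
        F = random_frequency_matrix(rng, 15)
        table = ir.build_lookup(F)
        for model in ("tau3", "combined"):
            for mode in ("binary", "weighted"):
                vec = ir.score_matrix(F, table, model=model, mode=mode)
                scal = [
                    ir.score_assessment(F.values[i], table, model, mode).value
                    for i in range(F.n_assessments)
                ]
                np.testing.assert_allclose(vec, scal)

    def test_raising_a_probability_cannot_lower_scores(self):
        """Monotonicity: pushing any cell above theta never decreases a score."""
        rng = np.random.default_rng(11)
        F = random_frequency_matrix(rng, 20)
        table = ir.build_lookup(F)
        before = ir.score_matrix(F, table, "combined", "binary")
        probs = table.probabilities.copy()
        low = np.argwhere(np.isnan(probs) | (probs < table.theta))
        for cell in low[:: max(1, len(low) // 10)]:
            probs2 = probs.copy()
            probs2[tuple(cell)] = 1.0
            bumped = ir.LookupTable(
                probabilities=probs2, variant=table.variant, theta=table.theta,
                n_control=table.n_control, n_risk=table.n_risk,
            )
            after = ir.score_matrix(F, bumped, "combined", "binary")
            assert (after >= before).all()


def brute_force_lookup(F, labels, variant="normalized-ratio"):
    """Straight-from-the-definitions lookup table: nested loops over i, tau, ch, j."""
    probs = np.full((5, 18, 5), np.nan)
    for tau in range(1, 6):
        for ch in range(1, 19):
            hist = {"control": [0] * 5, "risk": [0] * 5}
            for i in range(F.n_assessments):
                f = int(F.values[i, tau - 1, ch - 1])
                if f == 0:
                    continue
                j = ir.bin_index(f)
                hist["risk" if labels[i] == 1 else "control"][j - 1] += 1
            for j in range(1, 6):
                n_c, n_r = hist["control"][j - 1], hist["risk"][j - 1]
                if variant == "normalized-ratio":
                    tot_c, tot_r = sum(hist["control"]), sum(hist["risk"])
                    h_c = n_c / tot_c if tot_c else 0.0
                    h_r = n_r / tot_r if tot_r else 0.0
                else:
                    h_c, h_r = n_c, n_r
                if h_c + h_r > 0:
                    probs[tau - 1, ch - 1, j - 1] = h_r / (h_c + h_r)
    return probs


def brute_force_score(f_row, probs, theta, windows, mode):
    total = 0.0
    for tau in windows:
        for ch in range(1, 19):
            f = int(f_row[tau - 1, ch - 1])
            if f == 0:
                continue
            pt = probs[tau - 1, ch - 1, ir.bin_index(f) - 1]
            if not np.isnan(pt) and pt >= theta:
                total += pt if mode == "weighted" else 1.0
    return total


class TestBruteForceOracle:
    """On tiny cohorts the implementation must match a from-the-definitions
    recomputation exactly."""

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("variant", ["normalized-ratio", "raw-ratio"])
    def test_lookup_matches_nested_loops(self, seed, variant):
        rng = np.random.default_rng(seed)
        F = random_frequency_matrix(rng, int(rng.integers(4, 21)))
        table = ir.build_lookup(F, variant=variant)
        expected = brute_force_lookup(F, F.labels, variant)
        np.testing.assert_array_equal(
            np.isnan(table.probabilities), np.isnan(expected)
        )
        defined = ~np.isnan(expected)
        np.testing.assert_allclose(
            table.probabilities[defined], expected[defined], rtol=0, atol=0
        )

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("mode", ["binary", "weighted"])
    def test_scores_match_nested_loops(self, seed, mode):
        rng = np.random.default_rng(100 + seed)
        F = random_frequency_matrix(rng, int(rng.integers(4, 21)))
        table = ir.build_lookup(F)
        for model, windows in [("tau2", [2]), ("combined", [1, 2, 3, 4, 5])]:
            for i in range(F.n_assessments):
                got = ir.score_assessment(F.values[i], table, model, mode).value
                want = brute_force_score(
                    F.values[i], table.probabilities, table.theta, windows, mode
                )
                assert got == want
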