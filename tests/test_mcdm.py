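"""Criteria weighting and TOPSIS ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exante.mcdm import (
    apply_weights,
    closeness_index,
    derive_criteria_weights,
    euclidean_distances,
    ideal_solutions,
    indicator_ratios,
    normalize_decision_matrix,
    rank_technologies,
    topsis,
)
from exante.types import CriteriaWeights, DecisionMatrix, IndicatorSet


def brute_force_topsis(a, weights, directions):
    """Straight-line independent recomputation of all six steps in pure
    Python, kept free of the library's linear-algebra path."""
    n_rows, n_cols = len(a), len(a[0])
    norms = [math.sqrt(sum(a[i][j] ** 2 for i in range(n_rows))) for j in range(n_cols)]
    v = [[weights[j] * a[i][j] / norms[j] for j in range(n_cols)] for i in range(n_rows)]
    v_plus, v_minus = [], []
    for j in range(n_cols):
        col = [v[i][j] for i in range(n_rows)]
        if directions[j] == "benefit":
            v_plus.append(max(col)); v_minus.append(min(col))
        else:
            v_plus.append(min(col)); v_minus.append(max(col))
    closeness = []
    for i in range(n_rows):
        s_plus = math.sqrt(sum((v[i][j] - v_plus[j]) ** 2 for j in range(n_cols)))
        s_minus = math.sqrt(sum((v[i][j] - v_minus[j]) ** 2 for j in range(n_cols)))
        closeness.append(1.0 if s_plus + s_minus == 0 else s_minus / (s_plus + s_minus))
    return closeness


def matrix(rows, directions=("benefit", "benefit", "cost")):
    return DecisionMatrix(
        tech_ids=tuple(f"t{i}" for i in range(len(rows))),
        directions=directions,
        a=tuple(tuple(r) for r in rows),
    )


class TestWeights:
    # published indicator-ratio rows and their normalized weights (2 dp)
    @pytest.mark.parametrize(
        "ratios, expected",
        [
            ((1.38, 0.98, 1.18), (0.39, 0.28, 0.33)),  # semi-arid W Africa
            ((0.97, 1.46, 1.54), (0.24, 0.37, 0.39)),  # dry sub-humid S Asia
            ((1.67, 0.58, 1.32), (0.47, 0.16, 0.37)),  # semi-arid E Africa
        ],
    )
    def test_published_ratio_rows_normalize_to_published_weights(self, ratios, expected):
        w = derive_criteria_weights(ratios).as_array()
        assert tuple(np.round(w, 2)) == expected

    def test_equal_ratios_give_equal_weights(self):
        w = derive_criteria_weights((1.0, 1.0, 1.0)).as_array()
        assert w == pytest.approx([1 / 3] * 3)

    def test_ratios_from_indicator_rows(self):
        region = IndicatorSet(region="r", ag_gdp_share=30, poverty_headcount=15, child_stunting=20)
        ref = IndicatorSet(region="ref", ag_gdp_share=15, poverty_headcount=30, child_stunting=20)
        assert indicator_ratios(region, ref) == pytest.approx([2.0, 0.5, 1.0])
        assert indicator_ratios(region, region) == pytest.approx([1.0, 1.0, 1.0])

    def test_zero_reference_indicator_rejected(self):
        region = IndicatorSet(region="r", ag_gdp_share=10, poverty_headcount=10, child_stunting=10)
        ref = IndicatorSet(region="ref", ag_gdp_share=0, poverty_headcount=10, child_stunting=10)
        with pytest.raises(ValueError, match="zero indicator"):
            indicator_ratios(region, ref)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(1e-6, 1e6))
    def test_scale_invariance(self, c):
        base = derive_criteria_weights((1.38, 0.98, 1.18)).as_array()
        scaled = derive_criteria_weights((c * 1.38, c * 0.98, c * 1.18)).as_array()
        assert scaled == pytest.approx(base, rel=1e-9)
        assert scaled.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_ratios_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            derive_criteria_weights((0.0, 0.0, 0.0))


class TestTopsisSteps:
    def test_vector_normalization_three_four_five(self):
        m = DecisionMatrix(
            tech_ids=("a", "b"),
            a=((3.0, 3.0, -3.0), (4.0, 4.0, 4.0)),
        )
        r = normalize_decision_matrix(m)
        assert r[:, 0] == pytest.approx([0.6, 0.8])
        assert r[:, 2] == pytest.approx([-0.6, 0.8])  # signs preserved

    def test_unit_column_norms_on_random_matrix(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(6, 3))
        m = matrix(a.tolist())
        r = normalize_decision_matrix(m)
        assert np.linalg.norm(r, axis=0) == pytest.approx([1.0, 1.0, 1.0])

    def test_zero_column_error_names_criterion(self):
        m = matrix([[1.0, 0.0, 2.0], [3.0, 0.0, 4.0]])
        with pytest.raises(ValueError, match="poverty_reduction"):
            normalize_decision_matrix(m)

    def test_weighting_zeroes_unweighted_columns(self):
        r = np.array([[0.6, 0.8, 0.1]])
        v = apply_weights(r, CriteriaWeights.from_array([1.0, 0.0, 0.0]))
        assert v[0] == pytest.approx([0.6, 0.0, 0.0])

    def test_published_weighted_row(self):
        # normalized row for the top technology in semi-arid W/C Africa times
        # the (unrounded) regional weights reproduces the published weighted
        # row to 1e-3
        w = derive_criteria_weights((1.38, 0.98, 1.18))
        v = apply_weights(np.array([[0.4532, 0.6027, -0.4722]]), w)
        assert v[0] == pytest.approx([0.1763, 0.1664, -0.1582], abs=1e-3)

    def test_renormalized_weights_leave_v_unchanged(self):
        r = np.array([[0.4, 0.5, -0.3], [0.2, 0.1, 0.6]])
        w = derive_criteria_weights((2.0, 1.0, 3.0))
        w2 = derive_criteria_weights((4.0, 2.0, 6.0))
        assert apply_weights(r, w) == pytest.approx(apply_weights(r, w2))

    def test_ideals_direction_aware(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        v_plus, v_minus = ideal_solutions(v, ("benefit", "benefit"))
        assert v_plus == pytest.approx([1.0, 1.0])
        assert v_minus == pytest.approx([0.0, 0.0])
        v_plus, v_minus = ideal_solutions(v, ("benefit", "cost"))
        assert v_plus == pytest.approx([1.0, 0.0])
        assert v_minus == pytest.approx([0.0, 1.0])

    def test_single_row_is_its_own_ideals(self):
        v = np.array([[0.3, -0.2, 0.1]])
        v_plus, v_minus = ideal_solutions(v, ("benefit", "benefit", "cost"))
        assert v_plus == pytest.approx(v[0])
        assert v_minus == pytest.approx(v[0])

    def test_published_worked_distance(self):
        # distance of the published weighted row to the negative ideal
        v = np.array([[0.1763, 0.1664, -0.1581]])
        s_plus, s_minus = euclidean_distances(
            v, np.array([0.1763, 0.1664, -0.1581]), np.array([0.0153, 0.0048, 0.0])
        )
        assert s_plus[0] == 0.0
        assert s_minus[0] == pytest.approx(0.2776, abs=5e-4)

    def test_distance_matches_hand_hypotenuse(self):
        v = np.array([[3.0, 0.0], [0.0, 4.0]])
        s_plus, _ = euclidean_distances(v, np.array([0.0, 0.0]), np.array([0.0, 0.0]))
        assert s_plus == pytest.approx([3.0, 4.0])

    def test_closeness_endpoints_and_midpoint(self):
        assert closeness_index(np.array([0.0]), np.array([0.2776]))[0] == 1.0
        assert closeness_index(np.array([0.5]), np.array([0.5]))[0] == 0.5
        assert closeness_index(np.array([0.7]), np.array([0.0]))[0] == 0.0

    def test_degenerate_point_defined_as_one(self):
        assert closeness_index(np.array([0.0]), np.array([0.0]))[0] == 1.0


class TestRanking:
    def test_descending_closeness(self):
        assert list(rank_technologies([1.0, 0.4, 0.7])) == [1, 3, 2]

    def test_ties_share_minimum_rank(self):
        # two equal-lowest technologies both take the last rank
        closeness = [0.9, 0.1, 0.1, 0.5]
        assert list(rank_technologies(closeness)) == [1, 3, 3, 2]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_max_closeness_always_rank_one(self, closeness):
        ranks = rank_technologies(closeness)
        assert ranks[int(np.argmax(closeness))] == 1


class TestEndToEnd:
    @settings(derandomize=True, max_examples=100)
    @given(
        st.integers(1, 4),
        st.integers(0, 2**32 - 1),
    )
    def test_matches_brute_force_recomputation(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.1, 50.0, size=(n, 3))
        a[:, 2] *= -1  # malnutrition column: negative = improvement
        w = derive_criteria_weights(rng.uniform(0.1, 2.0, size=3))
        m = matrix(a.tolist())
        res = topsis(m, w)
        expected = brute_force_topsis(
            a.tolist(), list(w.as_array()), list(m.directions)
        )
        assert res.closeness == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.01, 100.0), st.integers(0, 3), st.integers(0, 2**32 - 1))
    def test_ranking_invariant_to_column_rescaling(self, c, col, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.1, 10.0, size=(5, 3))
        a[:, 2] *= -1
        w = CriteriaWeights.from_array([0.5, 0.3, 0.2])
        base = topsis(matrix(a.tolist()), w)
        scaled = a.copy()
        scaled[:, col % 3] *= c
        res = topsis(matrix(scaled.tolist()), w)
        assert res.rank == base.rank

    def test_ranking_equivariant_under_row_permutation(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0.1, 10.0, size=(6, 3))
        a[:, 2] *= -1
        w = CriteriaWeights.from_array([0.4, 0.3, 0.3])
        perm = rng.permutation(6)
        base = topsis(matrix(a.tolist()), w)
        shuffled = topsis(matrix(a[perm].tolist()), w)
        assert list(shuffled.rank) == [base.rank[i] for i in perm]

    def test_dominant_and_dominated_technologies(self):
        # t0 best on every criterion, t2 worst on every criterion
        a = [[10.0, 100.0, -50.0], [5.0, 60.0, -20.0], [1.0, 10.0, 30.0]]
        res = topsis(matrix(a), CriteriaWeights.from_array([0.4, 0.3, 0.3]))
        assert res.closeness[0] == pytest.approx(1.0)
        assert res.rank[0] == 1
        assert res.closeness[2] == pytest.approx(0.0)
        assert res.rank[2] == 3
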