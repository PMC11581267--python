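"""Criteria weighting and TOPSIS ranking.

Weights come from regional indicator ratios: a dryland region's share of
agriculture in GDP, poverty headcount and child-stunting rate are each
divided by the same indicator for its reference region (sub-Saharan Africa
for African drylands, South Asia for South-Asian drylands), and the three
ratios are normalized to sum to one.

TOPSIS (Technique for Order Preference by Similarity to an Ideal Solution)
then ranks technologies in six steps: vector-normalize each criterion
column, apply the weights, form the positive and negative ideal solutions
(best and worst weighted value per criterion, direction-aware), compute
Euclidean distances S+ and S− of each technology to the two ideals, form
the closeness index C+ = S− / (S− + S+) ∈ [0, 1], and rank by descending
closeness.  Ties share the minimum (competition) rank.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .types import CriteriaWeights, DecisionMatrix, Direction, IndicatorSet, TopsisResult

__all__ = [
    "indicator_ratios",
    "derive_criteria_weights",
    "normalize_decision_matrix",
    "apply_weights",
    "ideal_solutions",
    "euclidean_distances",
    "closeness_index",
    "rank_technologies",
    "topsis",
]

logger = logging.getLogger(__name__)


def indicator_ratios(region: IndicatorSet, reference: IndicatorSet) -> np.ndarray:
    """Elementwise region/reference indicator ratios (AgGDP share, poverty,
    stunting)."""
    ref = reference.as_array()
    if np.any(ref <= 0):
        raise ValueError(
            f"reference region {reference.region!r} has a zero indicator; "
            "ratios are undefined"
        )
    return region.as_array() / ref


def derive_criteria_weights(ratios: Sequence[float]) -> CriteriaWeights:
    """Normalize three indicator ratios to criteria weights summing to one."""
    r = np.asarray(ratios, dtype=float)
    if r.shape != (3,):
        raise ValueError(f"expected 3 ratios, got shape {r.shape}")
    if np.any(r < 0):
        raise ValueError("indicator ratios must be non-negative")
    total = r.sum()
    if total <= 0:
        raise ValueError("all indicator ratios are zero; weights undefined")
    return CriteriaWeights.from_array(r / total)


def normalize_decision_matrix(m: DecisionMatrix) -> np.ndarray:
    """Vector normalization: r_ij = a_ij / sqrt(Σ_i a_ij²), signs preserved."""
    a = m.as_array()
    norms = np.sqrt(np.sum(a**2, axis=0))
    for j, norm in enumerate(norms):
        if norm == 0:
            raise ValueError(
                f"criterion {m.criteria[j]!r} is zero for every technology; "
                "vector normalization undefined"
            )
    return a / norms


def apply_weights(r: np.ndarray, w: CriteriaWeights) -> np.ndarray:
    """Weighted normalized matrix v_ij = w_j · r_ij."""
    r = np.asarray(r, dtype=float)
    weights = w.as_array()
    if r.ndim != 2 or r.shape[1] != weights.shape[0]:
        raise ValueError(
            f"matrix has {r.shape[1] if r.ndim == 2 else '?'} criteria, "
            f"weights have {weights.shape[0]}"
        )
    return r * weights


def ideal_solutions(
    v: np.ndarray,
    directions: Sequence[Direction],
) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative ideal vectors, direction-aware per criterion.

    Benefit criteria contribute their column maximum to the positive ideal;
    cost criteria (here the malnutrition-change column, where more negative
    is better) contribute their minimum.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("empty weighted matrix")
    v_plus = np.empty(v.shape[1])
    v_minus = np.empty(v.shape[1])
    for j, direction in enumerate(directions):
        if direction == "benefit":
            v_plus[j], v_minus[j] = v[:, j].max(), v[:, j].min()
        elif direction == "cost":
            v_plus[j], v_minus[j] = v[:, j].min(), v[:, j].max()
        else:
            raise ValueError(f"unknown criterion direction: {direction!r}")
    return v_plus, v_minus


def euclidean_distances(
    v: np.ndarray,
    v_plus: np.ndarray,
    v_minus: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-technology distances to the positive and negative ideals."""
    v = np.asarray(v, dtype=float)
    s_plus = np.sqrt(np.sum((v - np.asarray(v_plus)) ** 2, axis=1))
    s_minus = np.sqrt(np.sum((v - np.asarray(v_minus)) ** 2, axis=1))
    return s_plus, s_minus


def closeness_index(s_plus: np.ndarray, s_minus: np.ndarray) -> np.ndarray:
    """C+ = S− / (S− + S+).  A technology coinciding with both ideals (a
    single-point degenerate matrix) is defined as closeness 1."""
    s_plus = np.asarray(s_plus, dtype=float)
    s_minus = np.asarray(s_minus, dtype=float)
    total = s_plus + s_minus
    degenerate = total == 0
    if np.any(degenerate):
        logger.warning(
            "degenerate TOPSIS matrix: %d technologies coincide with both "
            "ideals; their closeness is defined as 1",
            int(degenerate.sum()),
        )
    out = np.ones_like(total)
    np.divide(s_minus, total, out=out, where=~degenerate)
    return out


def rank_technologies(closeness: Sequence[float]) -> np.ndarray:
    """Competition ranks by descending closeness; ties share the minimum rank."""
    c = np.asarray(closeness, dtype=float)
    if c.size == 0:
        raise ValueError("no closeness values to rank")
    # rank = 1 + number of strictly better technologies
    return 1 + np.sum(c[None, :] > c[:, None], axis=1)


def topsis(m: DecisionMatrix, w: CriteriaWeights) -> TopsisResult:
    """Run all six TOPSIS steps on a decision matrix and return the full trace."""
    r = normalize_decision_matrix(m)
    v = apply_weights(r, w)
    v_plus, v_minus = ideal_solutions(v, m.directions)
    s_plus, s_minus = euclidean_distances(v, v_plus, v_minus)
    closeness = closeness_index(s_plus, s_minus)
    rank = rank_technologies(closeness)
    return TopsisResult(
        tech_ids=m.tech_ids,
        r=tuple(tuple(row) for row in r),
        v=tuple(tuple(row) for row in v),
        v_plus=tuple(v_plus),
        v_minus=tuple(v_minus),
        s_plus=tuple(float(x) for x in s_plus),
        s_minus=tuple(float(x) for x in s_minus),
        closeness=tuple(float(x) for x in closeness),
        rank=tuple(int(x) for x in rank),
    )
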