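"""Hierarchy metrics: ADI, tie-aware ranks, FDI, unknown relations,
aggression fractions — checked against independent brute-force oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domhier.core import GroupComposition, InteractionMatrix
from domhier.metrics import (
    aggression_fractions,
    average_dominance_index,
    average_dominance_index_exact,
    fdi_success_counts,
    female_dominance_index,
    rank_individuals,
    summarize_hierarchy,
    unknown_relation_proportion,
)
from domhier.synth import LatentModelParams, generate_interaction_matrix

from helpers import oracle_adi, oracle_fdi, oracle_ranks, oracle_unknown


def test_adi_hand_example(toy_matrix):
    adi = average_dominance_index(toy_matrix)
    assert adi == pytest.approx([0.75, 0.625, 0.0])
    exact = average_dominance_index_exact(toy_matrix)
    assert exact == [Fraction(3, 4), Fraction(5, 8), Fraction(0)]


def test_adi_bounds_and_exclusions():
    # a round-robin winner has ADI 1
    counts = np.array([[0, 2, 2], [0, 0, 1], [0, 1, 0]])
    m = InteractionMatrix(["m1", "f1", "f2"], ["male", "female", "female"], counts)
    assert average_dominance_index(m)[0] == 1.0
    # an isolated individual has undefined ADI and stays unranked
    counts = np.array([[0, 3, 0], [1, 0, 0], [0, 0, 0]])
    m = InteractionMatrix(["m1", "f1", "f2"], ["male", "female", "female"], counts)
    adi = average_dominance_index(m)
    assert np.isnan(adi[2]) and not np.isnan(adi[:2]).any()
    ranks = rank_individuals(adi)
    assert np.isnan(ranks[2]) and list(ranks[:2]) == [1, 2]


def test_adi_rejects_tiny_matrix():
    m = InteractionMatrix(["m1"], ["male"], np.zeros((1, 1), dtype=int))
    with pytest.raises(ValueError):
        average_dominance_index(m)


def test_ranks_ties_share_best_rank():
    ranks = rank_individuals([0.9, 0.9, 0.3])
    assert list(ranks) == [1, 1, 3]
    assert list(rank_individuals([0.75, 0.625, 0.0])) == [1, 2, 3]
    with pytest.raises(ValueError):
        rank_individuals([np.nan, np.nan])


def test_fdi_examples(toy_matrix):
    # all females above all males
    assert female_dominance_index([3, 4, 1, 2], ["male", "male", "female", "female"]) == 1.0
    # single male on top of four females (cf. a 1-male field group)
    ranks = [1, 2, 3, 4, 5]
    sexes = ["male", "female", "female", "female", "female"]
    assert female_dominance_index(ranks, sexes) == 0.0
    assert fdi_success_counts(ranks, sexes) == (0, 4)
    # from the ADI toy example: the male ranks first, no female outranks him
    adi = average_dominance_index(toy_matrix)
    r = rank_individuals(adi)
    assert female_dominance_index(r, toy_matrix.sexes) == 0.0
    assert fdi_success_counts(r, toy_matrix.sexes) == (0, 2)


def test_fdi_success_counts_saturated():
    ranks = [1, 2, 3, 4, 5, 6, 7]
    sexes = ["female"] * 5 + ["male"] * 2
    assert fdi_success_counts(ranks, sexes) == (10, 10)
    assert female_dominance_index(ranks, sexes) == 1.0


def test_fdi_tie_weight():
    ranks = [1, 1, 2]
    sexes = ["male", "female", "female"]
    assert female_dominance_index(ranks, sexes, tie_weight=0.0) == 0.0
    assert female_dominance_index(ranks, sexes, tie_weight=0.5) == 0.25


def test_fdi_requires_both_sexes():
    with pytest.raises(ValueError):
        female_dominance_index([1, 2], ["male", "male"])


def test_unknown_relation_proportion():
    full = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    m = InteractionMatrix(["m1", "f1", "f2"], ["male", "female", "female"], full)
    assert unknown_relation_proportion(m) == 0.0
    one_silent = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    m = InteractionMatrix(["m1", "f1", "f2"], ["male", "female", "female"], one_silent)
    assert unknown_relation_proportion(m) == pytest.approx(1 / 3)
    empty = InteractionMatrix(
        ["m1", "f1"], ["male", "female"], np.zeros((2, 2), dtype=int)
    )
    assert unknown_relation_proportion(empty) == 1.0


def test_aggression_fractions_toy():
    # male acts: 3 at males, 1 at females; female acts: 2 at males, 2 at females
    acts = np.array(
        [
            [0, 3, 1, 0],
            [0, 0, 0, 0],
            [2, 0, 0, 2],
            [0, 0, 0, 0],
        ]
    )
    sexes = ["male", "male", "female", "female"]
    f = aggression_fractions(acts, sexes)
    assert f.mm == pytest.approx(0.75) and f.fm == pytest.approx(0.5)
    assert not f.mm_excluded


def test_aggression_fractions_edge_cases():
    # males attack only males, females only females
    acts = np.array([[0, 5, 0], [3, 0, 0], [0, 0, 0]])
    f = aggression_fractions(acts, ["male", "male", "female"])
    assert f.mm == 1.0 and f.fm is None  # no female acts at all
    # single-male group: the male-male fraction is excluded
    acts = np.array([[0, 1, 1], [2, 0, 2], [1, 1, 0]])
    f = aggression_fractions(acts, ["male", "female", "female"])
    assert f.mm is None and f.mm_excluded
    assert f.fm == pytest.approx(3 / 6)  # 3 female-to-male acts of 6 female acts


@st.composite
def small_matrices(draw):
    n = draw(st.integers(2, 4))
    sexes = draw(
        st.lists(st.sampled_from(["male", "female"]), min_size=n, max_size=n).filter(
            lambda s: "male" in s and "female" in s
        )
    )
    cells = draw(
        st.lists(st.integers(0, 2), min_size=n * n, max_size=n * n)
    )
    counts = np.array(cells).reshape(n, n)
    np.fill_diagonal(counts, 0)
    ids = [("m" if s == "male" else "f") + str(i) for i, s in enumerate(sexes)]
    return InteractionMatrix(ids, sexes, counts)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(small_matrices())
def test_metrics_match_enumeration_oracle(m):
    """ADI, ranks, FDI and unknown proportion agree with direct brute-force
    computation from the definitions on all small matrices."""
    adi = average_dominance_index(m)
    oadi = oracle_adi(m.counts)
    for a, o in zip(adi, oadi):
        if o is None:
            assert np.isnan(a)
        else:
            assert a == pytest.approx(o)
        if o is not None:
            assert 0.0 <= a <= 1.0
    if all(o is None for o in oadi):
        return
    ranks = rank_individuals(adi)
    oranks = oracle_ranks(oadi)
    for r, o in zip(ranks, oranks):
        assert (o is None and np.isnan(r)) or r == o
    sex_of_ranked = [s for s, o in zip(m.sexes, oranks) if o is not None]
    if "male" in sex_of_ranked and "female" in sex_of_ranked:
        fdi = female_dominance_index(ranks, m.sexes)
        assert fdi == pytest.approx(oracle_fdi(oranks, m.sexes))
        assert 0.0 <= fdi <= 1.0
        succ, tot = fdi_success_counts(ranks, m.sexes)
        assert succ <= tot
        assert fdi == pytest.approx(oracle_fdi(oranks, m.sexes, tie_weight=0.0))
    assert unknown_relation_proportion(m) == pytest.approx(oracle_unknown(m.counts))


def test_fdi_sex_swap_complementarity():
    """Without ties or unranked individuals, swapping the sex labels maps
    the FDI to its complement."""
    rng = np.random.default_rng(77)
    params = LatentModelParams(encounter_rate=6.0, steepness=2.0)
    checked = 0
    for seed in range(30):
        m, _ = generate_interaction_matrix(GroupComposition(3, 3), params, seed)
        adi = average_dominance_index(m)
        if np.isnan(adi).any() or len(np.unique(np.round(adi, 9))) < len(adi):
            continue  # ties or unranked: identity does not apply
        ranks = rank_individuals(adi)
        fdi = female_dominance_index(ranks, m.sexes)
        swapped = ["male" if s == "female" else "female" for s in m.sexes]
        fdi_swapped = female_dominance_index(ranks, swapped)
        assert fdi_swapped == pytest.approx(1.0 - fdi)
        checked += 1
    assert checked >= 10


def test_rank_order_recovers_strong_latent_hierarchy():
    """With a steep latent hierarchy and dense sampling, the ADI ranking
    recovers the latent strength order (high Spearman correlation)."""
    from scipy.stats import spearmanr

    params = LatentModelParams(encounter_rate=8.0, steepness=3.0)
    rhos = []
    for seed in range(100):
        m, s = generate_interaction_matrix(GroupComposition(4, 4), params, seed)
        adi = average_dominance_index(m)
        if np.isnan(adi).any():
            continue
        rho, _ = spearmanr(adi, s)
        rhos.append(rho)
    assert np.mean(rhos) > 0.9


def test_summarize_hierarchy_bundles_consistently(toy_matrix):
    s = summarize_hierarchy(toy_matrix)
    assert s.fdi == 0.0 and (s.fdi_successes, s.fdi_total) == (0, 2)
    assert s.unknown_proportion == pytest.approx(1 / 3)
    assert s.mm_excluded  # single male
    assert s.fdi_successes / s.fdi_total == pytest.approx(s.fdi)
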