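"""Cumulative weight functions: induction, intervals, swap, medians, points."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import psrecon as pr
from conftest import TABLE_U, TABLE_V

instances = st.builds(
    lambda n, h, frac, seed: pr.random_instance(n, h, round(frac * n), seed),
    n=st.integers(1, 10),
    h=st.integers(1, 3),
    frac=st.floats(0, 1),
    seed=st.integers(0, 2**31 - 1),
)


def test_star_pairing():
    assert pr.star(1, 3) == 2
    assert pr.star(6, 3) == 5
    for m in range(1, 7):
        assert pr.star(pr.star(m, 3), 3) == m
    with pytest.raises(ValueError):
        pr.star(7, 3)


def test_induced_cwf_matches_reference_tables(f_U, g_V):
    for m, row in TABLE_U.items():
        assert tuple(f_U.component(m)) == row
    for m, row in TABLE_V.items():
        assert tuple(g_V.component(m)) == row
    # the rotational constraint pins the half-cell a printed table got wrong
    assert f_U.component(5)[5] == 4
    assert f_U.component(5)[5] + f_U.component(6)[1] == f_U.w_bar


def test_induce_cwf_rejects_mixed_weights_and_handles_flat():
    with pytest.raises(ValueError):
        pr.induce_cwf(pr.StringMultiset.from_strings(["01", "11"]))
    flat = pr.induce_cwf(pr.StringMultiset.from_strings(["0000"]))
    assert (flat.values == 0).all()


def test_strings_of_cwf_round_trip(U, f_U):
    assert pr.strings_of_cwf(f_U) == U
    assert tuple(np.diff(f_U.component(1))) == (1, 1, 0, 1, 0, 1)  # 110101


def test_maximal_intervals_examples(f_U):
    assert pr.maximal_intervals(f_U, 1, 6) == [(1, 2)]
    assert pr.maximal_intervals(f_U, 2, 6) == [(1, 1), (4, 4)]
    assert pr.maximal_intervals(f_U, 3, 1) == []  # identical components
    assert pr.maximal_intervals(f_U, 2, 2) == []  # diagonal is vacuous


def test_swap_examples(f_U, U, M_U):
    # swapping f1 with f6 on [1,2] turns the first string into the reversal
    # of the third; the result equals {011101,110101,110101} up to reversal
    g = pr.swap(f_U, (1, 2), 1, 6)
    assert (g.component(1) == f_U.component(6)).all()
    assert pr.canonical_class(pr.strings_of_cwf(g)) == pr.canonical_class(
        ["011101", "110101", "110101"]
    )
    assert pr.is_solution(g, M_U)

    # swapping f2 with f6 on {1} makes the third string a palindrome
    g2 = pr.swap(f_U, (1, 1), 2, 6)
    X = pr.strings_of_cwf(g2)
    assert X == pr.StringMultiset.from_strings(["110110", "110101", "101101"])
    assert "101101" in X.members and "101101" == pr.reverse_string("101101")
    assert pr.is_solution(g2, M_U)

    # the swap is an involution
    assert pr.swap(g2, (1, 1), 2, 6) == f_U
    with pytest.raises(ValueError):
        pr.swap(f_U, (2, 3), 1, 6)  # not a maximal interval


def test_is_solution(f_U, M_U, U, M_V):
    assert pr.is_solution(f_U, M_U)
    with pytest.raises(ValueError):
        pr.is_solution(f_U, M_V)  # dimension mismatch
    # perturbing one interior cell (keeping unit steps) breaks the counts
    values = np.array(f_U.values)
    values[2, 0] = 1
    broken = pr.CWF(n=6, h=3, values=values, w_bar=None)
    assert not pr.is_solution(broken, M_U)


def test_median_groups(f_U, g_V):
    mg = pr.median_groups(g_V)
    assert mg.groups[4] == frozenset({5, 6, 7, 8})  # A(w̄/2) for V
    assert mg.groups[2] == frozenset({1, 4}) and mg.groups[6] == frozenset({2, 3})
    # for U (n=6) every component passes through weight 2 at the midpoint
    assert pr.median_groups(f_U).groups[4] == frozenset(range(1, 7))
    ones = pr.median_groups(pr.induce_cwf(pr.StringMultiset.from_strings(["11"])))
    assert ones.groups[2] == frozenset({1, 2})


def test_classify_points(M_V):
    pc = pr.classify_points(M_V)
    g1_graph = {(l, w) for l, w in enumerate((0, 1, 1, 1, 1, 2, 3, 4))}
    assert {(5, 2), (6, 3)} <= pc.branching and {(5, 2), (6, 3)} <= g1_graph
    assert {(1, 1), (2, 1)} <= pc.merging and {(1, 1), (2, 1)} <= g1_graph
    # (3,2) is the only branching point with l <= floor(7/2) on the graph of g7
    g7_low = {(1, 1), (2, 1), (3, 2)}
    assert {p for p in pc.branching if p[0] <= 3} & g7_low == {(3, 2)}
    # a single deterministic path has no branching or merging points
    pc1 = pr.classify_points(pr.composition_multiset(["1111"]))
    assert not pc1.branching and not pc1.merging


@settings(derandomize=True, max_examples=50, deadline=None)
@given(U=instances)
def test_induced_cwf_is_valid_solution_with_even_middle_group(U):
    M = pr.composition_multiset(U)
    f = pr.induce_cwf(U)
    f.validate()
    assert pr.is_solution(f, M)
    middle = pr.median_groups(f).groups.get(f.w_bar, frozenset())
    assert len(middle) % 2 == 0
    assert all(pr.star(m, f.h) in middle for m in middle)
    assert pr.strings_of_cwf(f) == U


@settings(derandomize=True, max_examples=50, deadline=None)
@given(U=instances, m=st.integers(1, 20), m2=st.integers(1, 20))
def test_interval_mirror_symmetry(U, m, m2):
    """Partner-pair intervals mirror onto themselves; general pairs onto
    the starred pair (the two rotational-symmetry propositions)."""
    f = pr.induce_cwf(U)
    n, h = f.n, f.h
    m = 1 + (m - 1) % (2 * h)
    m2 = 1 + (m2 - 1) % (2 * h)
    ivs = pr.maximal_intervals(f, m, pr.star(m, h))
    mirrored = sorted((n - k2, n - k1) for k1, k2 in ivs)
    assert mirrored == ivs
    if m2 != m:
        ivs12 = [
            (k1, k2) for k1, k2 in pr.maximal_intervals(f, m, m2) if k2 <= n - 1
        ]
        starred = pr.maximal_intervals(f, pr.star(m, h), pr.star(m2, h))
        for k1, k2 in ivs12:
            assert (n - k2, n - k1) in starred


@settings(derandomize=True, max_examples=50, deadline=None)
@given(U=instances, pick=st.integers(0, 10**6))
def test_swap_preserves_solutions(U, pick):
    """Any swap on a maximal interval keeps the CWF a solution to M."""
    f = pr.induce_cwf(U)
    M = pr.composition_multiset(U)
    pairs = [
        (m1, m2, ivs)
        for m1 in range(1, 2 * f.h + 1)
        for m2 in range(m1 + 1, 2 * f.h + 1)
        for ivs in [pr.maximal_intervals(f, m1, m2)]
        if ivs
    ]
    if not pairs:
        return
    m1, m2, ivs = pairs[pick % len(pairs)]
    I = ivs[pick % len(ivs)]
    g = pr.swap(f, I, m1, m2)
    g.validate()
    assert pr.is_solution(g, M)
    assert pr.swap(g, I, m1, m2) == f
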