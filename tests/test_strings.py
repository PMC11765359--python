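"""Strings, affix compositions, composition-multiset grids, canonicalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import psrecon as pr

# seeded instance strategy shared by the property tests
instances = st.builds(
    lambda n, h, frac, seed: pr.random_instance(n, h, round(frac * n), seed),
    n=st.integers(1, 12),
    h=st.integers(1, 4),
    frac=st.floats(0, 1),
    seed=st.integers(0, 2**31 - 1),
)


def test_reverse_string_examples():
    assert pr.reverse_string("011101") == "101110"
    assert pr.reverse_string("101") == "101"
    assert pr.reverse_string(pr.reverse_string("110101")) == "110101"
    with pytest.raises(ValueError):
        pr.reverse_string("11a101")


def test_prefix_and_suffix_compositions():
    t = "110101"
    assert sorted(pr.prefix_compositions(t)) == sorted(
        [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (2, 4)]
    )
    assert sorted(pr.suffix_compositions(t)) == sorted(
        [(0, 1), (1, 1), (1, 2), (2, 2), (2, 3), (2, 4)]
    )
    assert pr.prefix_compositions("1") == [(0, 1)]
    assert pr.prefix_compositions("0000") == [(1, 0), (2, 0), (3, 0), (4, 0)]
    # palindromes have equal prefix and suffix compositions
    assert pr.prefix_compositions("0110") == pr.suffix_compositions("0110")
    # at length 5, 101110 has prefix composition (1,4) but suffix (2,3)
    assert pr.prefix_compositions("101110")[4] == (1, 4)
    assert pr.suffix_compositions("101110")[4] == (2, 3)


def test_composition_multiset_of_example_instance(M_U):
    expected = {
        (0, 1): 5, (1, 0): 1, (0, 2): 2, (1, 1): 4, (1, 2): 6,
        (1, 3): 4, (2, 2): 2, (1, 4): 1, (2, 3): 5, (2, 4): 6,
    }
    grid = {}
    for l in range(1, 7):
        for w in range(0, 7):
            if M_U.a[l, w]:
                grid[(l - w, w)] = int(M_U.a[l, w])
    assert grid == expected
    assert M_U.a[0, 0] == 6  # 2h, synthesized
    assert M_U.w_bar == 4


def test_composition_multiset_minimal_cases():
    M = pr.composition_multiset(["1"])
    assert M.a[0, 0] == 2 and M.a[1, 1] == 2 and M.w_bar == 1
    with pytest.raises(ValueError):
        pr.StringMultiset.from_strings(["01", "011"])  # mixed lengths
    with pytest.raises(ValueError):
        pr.StringMultiset.from_strings([])


def test_validation_passes_and_reports_violations(M_U):
    assert pr.validate_composition_multiset(M_U).ok
    # symmetric grid cell check: a[1,1] = a[5,3] = 5
    assert M_U.a[1, 1] == M_U.a[5, 3] == 5

    bad = np.array(M_U.a)
    bad[2, 1] += 1  # breaks the row sum (and the point symmetry)
    report = pr.validate_composition_multiset(
        pr.CompositionMultiset.from_grid(M_U.n, M_U.h, bad)
    )
    assert not report.ok
    assert any("row sum" in v for v in report.violations)

    above = np.zeros((3, 3), dtype=np.int64)
    above[1, 2] = 2  # w > l is impossible
    report = pr.validate_composition_multiset(
        pr.CompositionMultiset.from_grid(2, 1, above)
    )
    assert any("w>l" in v for v in report.violations)


def test_affix_flow_grid_values(M_U):
    grids = pr.affix_flow_grids(M_U)
    assert grids.c[3, 2] == 4
    assert grids.c[1, 1] == 5
    # diagonal: no affix of length l and weight l can keep weight l at l-1
    for l in range(1, M_U.n + 1):
        assert grids.b[l, l] == 0
        assert grids.c[l, l] == M_U.a[l, l]
    # s is the row suffix sum, anchored at 2h
    assert (grids.s[1:, 0] == 2 * M_U.h).all()


@settings(derandomize=True, max_examples=60, deadline=None)
@given(U=instances)
def test_grid_invariants_on_random_instances(U):
    """Row sums, point symmetry, flow decomposition, and the 2nh count."""
    M = pr.composition_multiset(U)
    assert pr.validate_composition_multiset(M).ok
    n, h, w_bar = M.n, M.h, M.w_bar
    assert int(M.a[1:].sum()) == 2 * n * h  # 2nh observed compositions
    for l in range(1, n + 1):
        assert int(M.a[l].sum()) == 2 * h
    for l in range(n + 1):
        for w in range(w_bar + 1):
            assert M.a[l, w] == M.a[n - l, w_bar - w]
    grids = pr.affix_flow_grids(M)
    for l in range(1, n + 1):
        for w in range(0, l + 1):
            assert M.a[l, w] == grids.b[l, w] + grids.c[l, w]
    for l in range(0, n):
        for w in range(0, l + 1):
            assert M.a[l, w] == grids.b[l + 1, w] + grids.c[l + 1, w + 1]


def test_canonical_class_examples(U):
    H3 = pr.StringMultiset.from_strings(["011101", "110101", "110101"])
    assert pr.canonical_class(U) == pr.canonical_class(H3)
    assert pr.canonical_class(U) == ("011101", "101011", "101011")
    # palindromes canonicalize to themselves
    assert pr.canonical_class(["0110", "1001"]) == ("0110", "1001")
    # {01,10} and {10,10} are reversals of each other
    assert pr.canonical_class(["01", "10"]) == pr.canonical_class(["10", "10"])


@settings(derandomize=True, max_examples=40, deadline=None)
@given(U=instances, flips=st.lists(st.integers(0, 3), max_size=4))
def test_canonical_class_invariant_under_member_reversal(U, flips):
    members = list(U.members)
    for i in flips:
        if i < len(members):
            members[i] = pr.reverse_string(members[i])
    assert pr.canonical_class(members) == pr.canonical_class(U)
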