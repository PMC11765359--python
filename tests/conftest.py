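import pytest

import psrecon as pr

# The two worked instances used throughout: a non-uniquely-reconstructible
# multiset U (three length-6 weight-4 strings) and a uniquely
# reconstructible one V (four length-7 weight-4 strings).
U_STRINGS = ("110101", "110101", "101110")
V_STRINGS = ("1000111", "1110001", "1100011", "1010011")

# Induced cumulative weight function of U, row per label m=1..6 over l=0..6.
# Cell (l=5, m=5) is 4 by direct computation from string 101110; a printed
# source shows 3 there, which breaks the rotational constraint
# f(5,5) + f(1,6) = 4 and is excluded as a typo by the builder of this table.
TABLE_U = {
    1: (0, 1, 2, 2, 3, 3, 4),
    2: (0, 1, 1, 2, 2, 3, 4),
    3: (0, 1, 2, 2, 3, 3, 4),
    4: (0, 1, 1, 2, 2, 3, 4),
    5: (0, 1, 1, 2, 3, 4, 4),
    6: (0, 0, 1, 2, 3, 3, 4),
}

# Induced CWF of V, row per label m=1..8 over l=0..7.
TABLE_V = {
    1: (0, 1, 1, 1, 1, 2, 3, 4),
    2: (0, 1, 2, 3, 3, 3, 3, 4),
    3: (0, 1, 2, 3, 3, 3, 3, 4),
    4: (0, 1, 1, 1, 1, 2, 3, 4),
    5: (0, 1, 2, 2, 2, 2, 3, 4),
    6: (0, 1, 2, 2, 2, 2, 3, 4),
    7: (0, 1, 1, 2, 2, 2, 3, 4),
    8: (0, 1, 2, 2, 2, 3, 3, 4),
}

# The three multisets compatible with M(U), up to reversal.
H1 = ("011101", "110011", "101101")
H2 = ("011011", "110101", "101101")
H3 = ("011101", "110101", "110101")


@pytest.fixture(scope="session")
def U():
    return pr.StringMultiset.from_strings(U_STRINGS)


@pytest.fixture(scope="session")
def V():
    return pr.StringMultiset.from_strings(V_STRINGS)


@pytest.fixture(scope="session")
def M_U(U):
    return pr.composition_multiset(U)


@pytest.fixture(scope="session")
def M_V(V):
    return pr.composition_multiset(V)


@pytest.fixture(scope="session")
def f_U(U):
    return pr.induce_cwf(U)


@pytest.fixture(scope="session")
def g_V(V):
    return pr.induce_cwf(V)
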