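"""Cumulative weight functions (CWFs) and their component-function algebra.

A CWF f(l, m) on {0..n} x [2h] records the running weight of every prefix
and suffix of a multiset of h strings: odd label 2j-1 tracks the prefixes of
string j, even label 2j its suffixes (this label convention matches the
paper-independent identity f(l, 2j-1) + f(n-l, 2j) = w_j, and every module
here relies on it).  A CWF is a *solution* to a composition multiset M when
it passes each grid point (l, w) exactly a[l, w] times.  The algebra in this
module - discrepancies and maximal intervals, the solution-preserving swap,
median-weight groups, branching/merging points - is what both the uniqueness
test and the exhaustive enumerator are built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .strings import (
    CompositionMultiset,
    StringMultiset,
    composition_multiset,
    affix_flow_grids,
    prefix_compositions,
)

__all__ = [
    "CWF",
    "MedianWeightIndex",
    "PointClassification",
    "star",
    "induce_cwf",
    "strings_of_cwf",
    "discrepancy",
    "maximal_intervals",
    "swap",
    "is_solution",
    "median_groups",
    "classify_points",
]


@dataclass(frozen=True)
class CWF:
    """A cumulative weight function.

    ``values[l, m-1]`` holds f(l, m) for l in 0..n and labels m in 1..2h.
    ``w_bar`` is the common weight for constant-weight CWFs, else ``None``.
    """

    n: int
    h: int
    values: np.ndarray = field(repr=False)
    w_bar: int | None

    def __post_init__(self):
        self.values.setflags(write=False)

    def component(self, m: int) -> np.ndarray:
        """The univariate component function f_m as an array over l=0..n."""
        if not 1 <= m <= 2 * self.h:
            raise ValueError(f"label {m} out of range [1, {2 * self.h}]")
        return self.values[:, m - 1]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CWF):
            return NotImplemented
        return (
            self.n == other.n
            and self.h == other.h
            and bool(np.array_equal(self.values, other.values))
        )

    def __hash__(self) -> int:
        return hash((self.n, self.h, self.values.tobytes()))

    def component_multiset(self) -> tuple[tuple[int, ...], ...]:
        """The 2h component functions as a sorted multiset of value tuples.

        This is the comparator for 'same CWF up to relabeling': two CWFs
        describe the same family of half-string behaviors iff these agree.
        """
        return tuple(sorted(tuple(int(x) for x in self.values[:, j])
                            for j in range(2 * self.h)))

    def validate(self) -> None:
        """Assert the three defining conditions of a CWF; raise ValueError else."""
        f = self.values
        if f.shape != (self.n + 1, 2 * self.h):
            raise ValueError("bad CWF shape")
        if (f[0] != 0).any():
            raise ValueError("f(0, m) != 0 for some m")
        steps = np.diff(f, axis=0)
        if not np.isin(steps, (0, 1)).all():
            raise ValueError("some step f(l,m) - f(l-1,m) outside {0, 1}")
        for j in range(1, self.h + 1):
            pair = f[:, 2 * j - 2] + f[::-1, 2 * j - 1]
            if not (pair == pair[0]).all():
                raise ValueError(f"f(l,{2 * j - 1}) + f(n-l,{2 * j}) not constant")
            if self.w_bar is not None and pair[0] != self.w_bar:
                raise ValueError(f"string {j} has weight {pair[0]} != {self.w_bar}")


def star(m: int, h: int) -> int:
    """The partner label m*: 2j-1 <-> 2j refer to the same underlying string."""
    if not 1 <= m <= 2 * h:
        raise ValueError(f"label {m} out of range [1, {2 * h}]")
    return m - 1 if m % 2 == 0 else m + 1


def induce_cwf(U: StringMultiset) -> CWF:
    """The CWF induced by a string multiset.

    f(l, 2j-1) is the weight of the length-l prefix of the j-th string and
    f(l, 2j) the weight of its length-l suffix; the multiset ordering of U
    fixes the string indexing.
    """
    if U.w_bar is None:
        raise ValueError("induce_cwf requires a constant-weight multiset")
    n, h = U.n, U.h
    values = np.zeros((n + 1, 2 * h), dtype=np.int64)
    for j, t in enumerate(U.members, start=1):
        for l, (_, w) in enumerate(prefix_compositions(t), start=1):
            values[l, 2 * j - 2] = w
        for l, (_, w) in enumerate(prefix_compositions(t[::-1]), start=1):
            values[l, 2 * j - 1] = w
    f = CWF(n=n, h=h, values=values, w_bar=U.w_bar)
    f.validate()
    return f


def strings_of_cwf(f: CWF) -> StringMultiset:
    """The multiset of strings corresponding to a CWF.

    Bit l of string j is the first difference f(l, 2j-1) - f(l-1, 2j-1).
    Inverse of :func:`induce_cwf` up to the pair ordering.
    """
    bits = np.diff(f.values[:, 0::2], axis=0)
    strings = ["".join("1" if b else "0" for b in bits[:, j]) for j in range(f.h)]
    return StringMultiset.from_strings(strings)


def discrepancy(f: CWF, m1: int, m2: int) -> set[int]:
    """D(m1, m2): the positions l in [n] where f_m1 and f_m2 differ."""
    d = f.component(m1) != f.component(m2)
    return {int(l) for l in np.nonzero(d)[0] if l >= 1}


def maximal_intervals(f: CWF, m1: int, m2: int) -> list[tuple[int, int]]:
    """The maximal runs [k1, k2] of the discrepancy between f_m1 and f_m2.

    Returned sorted and disjoint; they cover D(m1, m2) exactly.  For m1 == m2
    the discrepancy is empty and so is the result.
    """
    if m1 == m2:
        return []
    D = discrepancy(f, m1, m2)
    intervals: list[tuple[int, int]] = []
    for l in sorted(D):
        if intervals and intervals[-1][1] == l - 1:
            intervals[-1] = (intervals[-1][0], l)
        else:
            intervals.append((l, l))
    return [tuple(iv) for iv in intervals]


def swap(f: CWF, I: tuple[int, int], m1: int, m2: int) -> CWF:
    """The swap ϕ(f, I, m1, m2) exchanging component functions on an interval.

    Requires ``I = (k1, k2)`` to be a maximal interval between f_m1 and f_m2
    and f to be constant-weight.  When m2 != m1*, the values of f_m1 and
    f_m2 are exchanged on I and those of f_m1* and f_m2* on the mirrored
    interval [n-k2, n-k1]; when m2 = m1*, f_m1 and f_m2 are exchanged once on
    the union of I and its mirror.  The output is a valid CWF, and if f is a
    solution to some M then so is the output (the swap moves values between
    labels at fixed (l, w) cells, leaving all cell occupancies unchanged).
    """
    if f.w_bar is None:
        raise ValueError("swap requires a constant-weight CWF")
    k1, k2 = I
    if (k1, k2) not in maximal_intervals(f, m1, m2):
        raise ValueError(
            f"{I} is not a maximal interval between f_{m1} and f_{m2}: "
            f"{maximal_intervals(f, m1, m2)}"
        )
    h = f.h
    m1s, m2s = star(m1, h), star(m2, h)
    g = np.array(f.values)
    span = range(k1, k2 + 1)
    mirror = range(f.n - k2, f.n - k1 + 1)
    if m2 == m1s:
        cells = sorted(set(span) | set(mirror))
        for l in cells:
            g[l, m1 - 1], g[l, m2 - 1] = g[l, m2 - 1], g[l, m1 - 1]
    else:
        for l in span:
            g[l, m1 - 1], g[l, m2 - 1] = g[l, m2 - 1], g[l, m1 - 1]
        for l in mirror:
            g[l, m1s - 1], g[l, m2s - 1] = g[l, m2s - 1], g[l, m1s - 1]
    out = CWF(n=f.n, h=f.h, values=g, w_bar=f.w_bar)
    out.validate()
    return out


def is_solution(f: CWF, M: CompositionMultiset) -> bool:
    """True iff f passes every grid point (l, w) exactly a[l, w] times.

    Equivalently, |A_f(l, w)| = a[l, w] for all (l, w) in {0..n}^2 where
    A_f(l, w) = {m : f(l, m) = w}.
    """
    if f.n != M.n or f.h != M.h:
        raise ValueError(
            f"dimension mismatch: CWF (n={f.n}, h={f.h}) vs M (n={M.n}, h={M.h})"
        )
    counts = np.zeros_like(M.a)
    for l in range(f.n + 1):
        vals, cnt = np.unique(f.values[l], return_counts=True)
        counts[l, vals] = cnt
    return bool(np.array_equal(counts, M.a))


@dataclass(frozen=True)
class MedianWeightIndex:
    """Median weights of the component functions, stored doubled.

    ``doubled_median[m] = f(floor(n/2), m) + f(ceil(n/2), m)`` (twice the
    median weight; kept integral to avoid fractional comparisons), and
    ``groups`` maps each doubled median value to the label set A(w).
    """

    doubled_median: dict[int, int]
    groups: dict[int, frozenset[int]]


def median_groups(f: CWF) -> MedianWeightIndex:
    """Group the 2h labels by median weight.

    For a constant-weight CWF, |A(w̄/2)| is even and closed under the star
    pairing, since f_m and f_m* are 180-degree rotations of each other about
    (n/2, w̄/2).
    """
    lo, hi = f.n // 2, (f.n + 1) // 2
    doubled = {
        m: int(f.values[lo, m - 1] + f.values[hi, m - 1])
        for m in range(1, 2 * f.h + 1)
    }
    groups: dict[int, set[int]] = {}
    for m, dm in doubled.items():
        groups.setdefault(dm, set()).add(m)
    return MedianWeightIndex(
        doubled_median=doubled,
        groups={dm: frozenset(ms) for dm, ms in groups.items()},
    )


@dataclass(frozen=True)
class PointClassification:
    """Branching and merging grid points of a composition multiset.

    (l, w) is branching when b[l, w] > 0 and c[l, w] > 0 (some affixes keep
    weight w and some drop to w-1 as the length goes from l to l-1), and
    merging when b[l+1, w] > 0 and c[l+1, w+1] > 0.  These are properties of
    M itself: every solution CWF sees the same points.
    """

    branching: frozenset[tuple[int, int]]
    merging: frozenset[tuple[int, int]]


def classify_points(M: CompositionMultiset) -> PointClassification:
    """Identify all branching and merging points of M via the b/c grids."""
    grids = affix_flow_grids(M)
    b, c = grids.b, grids.c
    n = M.n
    branching = frozenset(
        (l, w)
        for l in range(1, n + 1)
        for w in range(1, l + 1)
        if b[l, w] > 0 and c[l, w] > 0
    )
    merging = frozenset(
        (l, w)
        for l in range(0, n)
        for w in range(0, n)
        if b[l + 1, w] > 0 and c[l + 1, w + 1] > 0
    )
    return PointClassification(branching=branching, merging=merging)
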