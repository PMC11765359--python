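"""Exhaustive enumeration of all string multisets compatible with M.

Constant weight makes each suffix component function the 180-degree rotation
of its prefix partner, so a solution CWF is determined by the behavior of
its 2h component functions on the lower half {0..floor(n/2)} together with a
pairing of "half strings" whose median weights sum to w̄.  The enumeration
therefore runs in two stages:

* scan stage — starting from the midpoint occupancies (the a-row at n/2 for
  even n, the b/c columns at ceil(n/2) for odd n), sweep l from floor(n/2)
  down to 0, at each cell (l, w) enumerating every way of choosing how many
  members of each label group drop weight (a bounded integer-composition
  system with total c[l, w]); each completed sweep is a bookkeeping leaf
  whose groups are the distinct half strings with their multiplicities;

* assembly stage — for each leaf, group half strings by median weight and
  enumerate every pairing of complementary medians: a transportation-matrix
  system for median pairs (w, w̄-w) with w < w̄/2 and a symmetric
  even-diagonal system for the self-paired median w̄/2; each pairing is
  stitched into full strings by the rotational symmetry.

Label sets are represented obliviously (only sizes and value histories
matter), which collapses all symmetric relabelings; distinct leaves and
distinct pairings provably yield distinct multisets up to reversal, and a
defensive assertion converts any violation into a loud failure.  Worst-case
growth is exponential, so the search carries a configurable budget.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .cwf import CWF, is_solution
from .strings import (
    CompositionMultiset,
    ExplosionError,
    StringMultiset,
    affix_flow_grids,
    canonical_class,
    require_valid,
)

logger = logging.getLogger("psrecon")

__all__ = [
    "HalfGroup",
    "Bookkeeping",
    "ScanSplit",
    "initial_partition",
    "bounded_compositions",
    "transportation_matrices",
    "symmetric_even_diagonal_matrices",
    "scan",
    "group_half_profiles",
    "pairing_solutions",
    "assemble",
    "reconstruct_all",
    "DEFAULT_MAX_LEAVES",
]

DEFAULT_MAX_LEAVES = 10**6


@dataclass(frozen=True, order=True)
class HalfGroup:
    """A maximal set of labels sharing one half string.

    ``graph`` holds the component-function values at l = 0..floor(n/2);
    ``doubled_median`` is twice the median weight (kept integral so that the
    half-integer medians of odd n need no fractions); ``size`` is the number
    of labels (component functions) with this behavior.
    """

    doubled_median: int
    graph: tuple[int, ...]
    size: int

    @property
    def half_string(self) -> str:
        """The half string spelled by the first differences of the graph."""
        return "".join(
            "1" if b - a else "0" for a, b in zip(self.graph, self.graph[1:])
        )


#: A completed scan leaf: the distinct half strings with multiplicities.
Bookkeeping = tuple[HalfGroup, ...]


@dataclass(frozen=True)
class ScanSplit:
    """Trace record of one bounded-composition system solved during a scan."""

    l: int
    w: int
    total: int
    bounds: tuple[int, ...]
    solutions: tuple[tuple[int, ...], ...]


def initial_partition(M: CompositionMultiset) -> dict[int, int]:
    """Sizes of the midpoint label partition, keyed by doubled median weight.

    For even n the component values at n/2 are read off the a-row directly;
    for odd n the b/c columns at ceil(n/2) separate the integer medians
    (weight kept across the midpoint) from the half-integer ones (weight
    dropped).  The returned mass must be symmetric under dm -> 2*w_bar - dm
    for a pairing to exist; asymmetry proves M invalid.
    """
    require_valid(M)
    n, w_bar = M.n, M.w_bar
    assert w_bar is not None
    parts: dict[int, int] = {}
    if n % 2 == 0:
        for w in range(w_bar + 1):
            if M.a[n // 2, w]:
                parts[2 * w] = int(M.a[n // 2, w])
    else:
        grids = affix_flow_grids(M)
        mid = (n + 1) // 2
        for w in range(w_bar + 1):
            if grids.b[mid, w]:
                parts[2 * w] = int(grids.b[mid, w])
            if grids.c[mid, w]:
                parts[2 * w - 1] = int(grids.c[mid, w])
    for dm, size in parts.items():
        if parts.get(2 * w_bar - dm, 0) != size:
            raise AssertionError(
                f"median-weight mass asymmetric: |P({dm}/2)|={size} but "
                f"|P({2 * w_bar - dm}/2)|={parts.get(2 * w_bar - dm, 0)}"
            )
    return parts


def bounded_compositions(total: int, bounds: tuple[int, ...]) -> list[tuple[int, ...]]:
    """All vectors x with sum(x) = total and 0 <= x_i <= bounds_i, in lex order.

    Returns the empty list when infeasible.
    """
    if total < 0:
        return []
    out: list[tuple[int, ...]] = []

    def rec(i: int, remaining: int, acc: tuple[int, ...]) -> None:
        if i == len(bounds):
            if remaining == 0:
                out.append(acc)
            return
        if remaining > sum(bounds[i:]):
            return
        for x in range(min(remaining, bounds[i]) + 1):
            rec(i + 1, remaining - x, acc + (x,))

    rec(0, total, ())
    return out


def transportation_matrices(
    row_sums: tuple[int, ...], col_sums: tuple[int, ...]
) -> list[tuple[tuple[int, ...], ...]]:
    """All nonnegative integer matrices with the given row and column sums.

    Enumerated row by row in lexicographic order of the flattened matrix.
    """
    if sum(row_sums) != sum(col_sums):
        return []
    out: list[tuple[tuple[int, ...], ...]] = []

    def rec(i: int, remaining_cols: tuple[int, ...], rows: tuple) -> None:
        if i == len(row_sums):
            out.append(rows)
            return
        for row in bounded_compositions(row_sums[i], remaining_cols):
            rec(
                i + 1,
                tuple(rc - x for rc, x in zip(remaining_cols, row)),
                rows + (row,),
            )

    rec(0, tuple(col_sums), ())
    return out


def symmetric_even_diagonal_matrices(
    sizes: tuple[int, ...],
) -> list[tuple[tuple[int, ...], ...]]:
    """All symmetric nonnegative matrices with even diagonal and given row sums.

    These encode self-pairings within the median-w̄/2 groups: entry (i, j)
    counts labels of group i paired with labels of group j, so the diagonal
    must be even (labels pair up within the group).  Enumerated over the
    upper triangle in lexicographic order.
    """
    r = len(sizes)
    out: list[tuple[tuple[int, ...], ...]] = []
    y = [[0] * r for _ in range(r)]

    def rec(i: int) -> None:
        if i == r:
            out.append(tuple(tuple(row) for row in y))
            return
        fixed = sum(y[j][i] for j in range(i))
        remaining = sizes[i] - fixed
        if remaining < 0:
            return
        # capacity left in each later row j > i
        caps = [sizes[j] - sum(y[k][j] for k in range(i)) for j in range(i + 1, r)]

        def fill(j: int, rem: int) -> None:
            if j == r:
                if rem == 0:
                    rec(i + 1)
                return
            cap = caps[j - i - 1]
            if j == i:
                choices = range(0, min(rem, remaining) + 1, 2)
            else:
                choices = range(0, min(rem, cap) + 1)
            for x in choices:
                y[i][j] = x
                y[j][i] = x
                fill(j + 1, rem - x)
            y[i][j] = 0
            if j != i:
                y[j][i] = 0

        # diagonal is its own capacity (bounded by remaining)
        caps = [remaining] + caps
        fill(i, remaining)

    rec(0)
    return out


def _initial_groups(M: CompositionMultiset) -> list[tuple[int, tuple[int, ...], int]]:
    """Partial groups (doubled_median, value history, size) at l = floor(n/2)."""
    n, w_bar = M.n, M.w_bar
    parts = initial_partition(M)
    groups = []
    for dm, size in sorted(parts.items()):
        # value at floor(n/2): dm/2 for integer medians, (dm-1)/2 below a
        # half-integer median (the weight drops across the midpoint).
        groups.append((dm, (dm // 2,), size))
    return groups


def scan(
    M: CompositionMultiset,
    max_leaves: int = DEFAULT_MAX_LEAVES,
    log: list[ScanSplit] | None = None,
) -> list[Bookkeeping]:
    """Enumerate all bookkeeping functions (half-string multisets) for M.

    Breadth-first from l = floor(n/2) down to 0, cell by cell with l and w
    both descending; at each cell (l, w) every bounded-composition solution
    of the drop equation sum_i x_i = c[l, w], x_i <= |J_i| spawns one
    successor.  Parts within a cell are ordered by (size desc, history) for
    reproducibility.  Pass ``log`` to record every system solved (used to
    inspect individual splits).  Raises :class:`ExplosionError` when the
    frontier exceeds ``max_leaves``.
    """
    require_valid(M)
    n, w_bar = M.n, M.w_bar
    assert w_bar is not None
    c = affix_flow_grids(M).c
    half = n // 2
    # a state is (processed, pending): pending groups still carry the value
    # history down to the current level l, processed ones down to l-1.
    states: list[tuple[tuple, tuple]] = [((), tuple(_initial_groups(M)))]
    for l in range(half, 0, -1):
        for w in range(w_bar, -1, -1):
            next_states = []
            for done, pending in states:
                cell = sorted(
                    (g for g in pending if g[1][0] == w),
                    key=lambda g: (-g[2], g[1], g[0]),
                )
                rest = tuple(g for g in pending if g[1][0] != w)
                if not cell:
                    if c[l, w]:
                        raise AssertionError(
                            f"no labels at cell (l={l}, w={w}) but c={int(c[l, w])}"
                        )
                    next_states.append((done, pending))
                    continue
                bounds = tuple(g[2] for g in cell)
                sols = bounded_compositions(int(c[l, w]), bounds)
                assert sols, f"no admissible split at (l={l}, w={w})"
                if log is not None:
                    log.append(
                        ScanSplit(
                            l=l, w=w, total=int(c[l, w]), bounds=bounds,
                            solutions=tuple(sols),
                        )
                    )
                for x in sols:
                    children = []
                    for (dm, hist, size), xi in zip(cell, x):
                        if xi:
                            children.append((dm, (w - 1,) + hist, xi))
                        if size - xi:
                            children.append((dm, (w,) + hist, size - xi))
                    next_states.append((done + tuple(children), rest))
            states = next_states
            if len(states) > max_leaves:
                raise ExplosionError(
                    f"scan frontier exceeded {max_leaves} states at (l={l}, w={w})"
                )
        # all pending groups consumed at this level; move down
        states = [((), done + rest) for done, rest in states]
    leaves: list[Bookkeeping] = []
    seen = set()
    for _, groups in states:
        assert all(g[1][0] == 0 for g in groups), "half graph not anchored at 0"
        leaf = tuple(
            sorted(HalfGroup(doubled_median=dm, graph=hist, size=size)
                   for dm, hist, size in groups)
        )
        keys = [(g.doubled_median, g.graph) for g in leaf]
        assert len(set(keys)) == len(keys), "duplicate half profiles in one leaf"
        assert leaf not in seen, "duplicate bookkeeping leaf"
        seen.add(leaf)
        leaves.append(leaf)
    logger.info("scan: n=%d h=%d -> %d bookkeeping leaf(s)", n, M.h, len(leaves))
    return leaves


def group_half_profiles(F: Bookkeeping) -> dict[int, list[HalfGroup]]:
    """Group a leaf's half profiles by doubled median weight.

    Groups within each median class are ordered by (size asc, graph), the
    ordering used for the rows/columns of the pairing systems.
    """
    R: dict[int, list[HalfGroup]] = {}
    for g in F:
        R.setdefault(g.doubled_median, []).append(g)
    for dm in R:
        R[dm].sort(key=lambda g: (g.size, g.graph))
    return R


#: One pairing choice: doubled median dm (<= w_bar doubled) -> integer matrix.
PairingSolution = dict[int, tuple[tuple[int, ...], ...]]


def pairing_solutions(
    R: dict[int, list[HalfGroup]],
    w_bar: int,
    max_solutions: int = DEFAULT_MAX_LEAVES,
) -> list[PairingSolution]:
    """All ways of pairing half strings of complementary median weights.

    For each doubled median dm < w̄ present, the matrices pair the groups of
    median dm/2 (rows) with those of median w̄ - dm/2 (columns) under a
    transportation system; dm = w̄ (median w̄/2) pairs within itself under a
    symmetric even-diagonal system.  The result is the Cartesian product
    over medians, each factor in deterministic lexicographic order.
    """
    per_dm: list[tuple[int, list]] = []
    for dm in sorted(R):
        if dm > w_bar:
            continue  # consumed as the column side of its partner
        partner = 2 * w_bar - dm
        if dm == w_bar:
            mats = symmetric_even_diagonal_matrices(
                tuple(g.size for g in R[dm])
            )
        else:
            mats = transportation_matrices(
                tuple(g.size for g in R[dm]),
                tuple(g.size for g in R.get(partner, [])),
            )
        assert mats, f"no feasible pairing for doubled median {dm}"
        per_dm.append((dm, mats))
    count = 1
    for _, mats in per_dm:
        count *= len(mats)
        if count > max_solutions:
            raise ExplosionError(f"more than {max_solutions} pairing solutions")
    solutions = []
    for combo in itertools.product(*(mats for _, mats in per_dm)):
        solutions.append({dm: mat for (dm, _), mat in zip(per_dm, combo)})
    return solutions


def _stitch(u: HalfGroup, v: HalfGroup, n: int, w_bar: int) -> list[int]:
    """Full prefix function from a half pair: u on the left, v rotated on the right."""
    assert u.doubled_median + v.doubled_median == 2 * w_bar, "median mismatch"
    half = n // 2
    return list(u.graph) + [w_bar - v.graph[n - l] for l in range(half + 1, n + 1)]


def assemble(
    F: Bookkeeping, y: PairingSolution, M: CompositionMultiset
) -> StringMultiset:
    """Stitch one pairing solution into a full string multiset.

    Each pair contributes one string: its prefix function follows the left
    half on {0..floor(n/2)} and the 180-degree rotation of the right half
    above the midpoint; bits are the first differences.  The assembled CWF
    is checked to be a solution to M.
    """
    n, h, w_bar = M.n, M.h, M.w_bar
    assert w_bar is not None
    R = group_half_profiles(F)
    prefix_functions: list[list[int]] = []
    for dm, mat in sorted(y.items()):
        rows = R[dm]
        cols = R[2 * w_bar - dm] if dm < w_bar else rows
        for i, row in enumerate(mat):
            for j, cnt in enumerate(row):
                if dm == w_bar:
                    if j < i:
                        continue  # symmetric: handled at (j, i)
                    pairs = cnt // 2 if i == j else cnt
                    if i == j:
                        assert cnt % 2 == 0, "odd diagonal in self-pairing"
                else:
                    pairs = cnt
                for _ in range(pairs):
                    prefix_functions.append(_stitch(rows[i], cols[j], n, w_bar))
    assert len(prefix_functions) == h, "pairing does not produce h strings"
    values = np.zeros((n + 1, 2 * h), dtype=np.int64)
    for j, pf in enumerate(sorted(prefix_functions), start=1):
        values[:, 2 * j - 2] = pf
        values[:, 2 * j - 1] = w_bar - values[::-1, 2 * j - 2]
    f = CWF(n=n, h=h, values=values, w_bar=w_bar)
    f.validate()
    assert is_solution(f, M), "assembled CWF is not a solution to M"
    bits = np.diff(values[:, 0::2], axis=0)
    return StringMultiset.from_strings(
        "".join("1" if b else "0" for b in bits[:, j]) for j in range(h)
    )


def reconstruct_all(
    M: CompositionMultiset, max_leaves: int = DEFAULT_MAX_LEAVES
) -> list[tuple[str, ...]]:
    """All string multisets compatible with M, as sorted canonical classes.

    Runs the scan stage, then the assembly stage for every bookkeeping leaf,
    and canonicalizes each assembled multiset up to reversal.  Distinctness
    of the classes is guaranteed by construction and asserted defensively.
    Raises :class:`ExplosionError` if the search exceeds ``max_leaves``
    (combined over scan states and pairing solutions).
    """
    require_valid(M)
    classes: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for F in scan(M, max_leaves=max_leaves):
        R = group_half_profiles(F)
        for y in pairing_solutions(R, M.w_bar, max_solutions=max_leaves):
            cls = canonical_class(assemble(F, y, M))
            assert cls not in seen, f"duplicate reconstructed class {cls}"
            seen.add(cls)
            classes.append(cls)
            if len(classes) > max_leaves:
                raise ExplosionError(f"more than {max_leaves} compatible classes")
    classes.sort()
    logger.info(
        "reconstruct_all: n=%d h=%d -> %d compatible class(es)", M.n, M.h, len(classes)
    )
    return classes
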