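"""Binary strings, affix compositions, and the composition-multiset grids.

The observable data of the reconstruction problem is the multiset M(U) of
compositions (zero-count, one-count pairs) of every prefix and every suffix
of every string in a multiset U of length-n, weight-w̄ binary strings.  This
module builds M(U) from strings, stores it as a dense integer grid a[l, w]
(the multiplicity of the composition (l-w, w)), derives the affix-flow grids
b, c, s that drive every downstream algorithm, validates candidate grids,
and canonicalizes string multisets up to reversal equivalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger("psrecon")

__all__ = [
    "Composition",
    "StringMultiset",
    "CompositionMultiset",
    "AffixFlowGrids",
    "ValidationReport",
    "InvalidCompositionsError",
    "ExplosionError",
    "reverse_string",
    "weight",
    "prefix_compositions",
    "suffix_compositions",
    "composition_multiset",
    "validate_composition_multiset",
    "affix_flow_grids",
    "canonical_string",
    "canonical_class",
]

#: A composition is the ordered pair (number of zeros, number of ones).
Composition = tuple[int, int]


class InvalidCompositionsError(ValueError):
    """Raised when a composition multiset cannot arise from any string multiset."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(str(report))


class ExplosionError(RuntimeError):
    """Raised when an enumeration exceeds its configured search budget."""


def _check_binary(t: str) -> str:
    if not t or any(ch not in "01" for ch in t):
        raise ValueError(f"not a nonempty binary string: {t!r}")
    return t


def reverse_string(t: str) -> str:
    """Return the reversal of a binary string (an involution preserving weight)."""
    return _check_binary(t)[::-1]


def weight(t: str) -> int:
    """Number of ones in ``t``."""
    return t.count("1")


def prefix_compositions(t: str) -> list[Composition]:
    """Compositions of all prefixes of ``t``, one per length j=1..n.

    Element j-1 of the result is ``(j - wt(t[:j]), wt(t[:j]))``.
    """
    _check_binary(t)
    out: list[Composition] = []
    w = 0
    for j, ch in enumerate(t, start=1):
        w += ch == "1"
        out.append((j - w, w))
    return out


def suffix_compositions(t: str) -> list[Composition]:
    """Compositions of all suffixes of ``t``, one per length j=1..n."""
    return prefix_compositions(reverse_string(t))


@dataclass(frozen=True, eq=False)
class StringMultiset:
    """A multiset of ``h`` binary strings sharing a common length ``n``.

    ``w_bar`` is the common weight when the multiset is constant-weight and
    ``None`` otherwise.  Members keep their construction order (the induced
    CWF labels strings in this order), but equality and hashing are
    order-insensitive: two StringMultisets compare equal iff they are equal
    as multisets.
    """

    members: tuple[str, ...]
    n: int
    h: int
    w_bar: int | None

    def __eq__(self, other) -> bool:
        if not isinstance(other, StringMultiset):
            return NotImplemented
        return sorted(self.members) == sorted(other.members)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.members)))

    @classmethod
    def from_strings(cls, strings: Iterable[str]) -> "StringMultiset":
        members = tuple(_check_binary(t) for t in strings)
        if not members:
            raise ValueError("empty string multiset")
        n = len(members[0])
        if any(len(t) != n for t in members):
            raise ValueError("strings have mixed lengths")
        weights = {weight(t) for t in members}
        w_bar = weights.pop() if len(weights) == 1 else None
        return cls(members=members, n=n, h=len(members), w_bar=w_bar)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def reversals(self) -> "StringMultiset":
        return StringMultiset.from_strings(reverse_string(t) for t in self.members)


@dataclass(frozen=True)
class CompositionMultiset:
    """The prefix-suffix composition multiset M as a dense grid.

    ``a[l, w]`` is the multiplicity of the composition ``(l - w, w)`` in M
    for l in 0..n, with the convention ``a[0, 0] = 2h``.  ``w_bar`` is the
    common string weight inferred from row l=n (the unique w with
    ``a[n, w] = 2h``), or ``None`` when no such w exists.
    """

    n: int
    h: int
    a: np.ndarray = field(repr=False)
    w_bar: int | None

    def __post_init__(self):
        self.a.setflags(write=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CompositionMultiset):
            return NotImplemented
        return (
            self.n == other.n
            and self.h == other.h
            and bool(np.array_equal(self.a, other.a))
        )

    def __hash__(self) -> int:
        return hash((self.n, self.h, self.a.tobytes()))

    def key(self) -> bytes:
        """A stable hashable serialization of the grid (used for grouping)."""
        return self.a.astype(np.int64).tobytes()

    @classmethod
    def from_grid(cls, n: int, h: int, a: np.ndarray) -> "CompositionMultiset":
        a = np.array(a, dtype=np.int64)
        if a.shape != (n + 1, n + 1):
            raise ValueError(f"grid must be {(n + 1, n + 1)}, got {a.shape}")
        a[0, 0] = 2 * h  # Definition-12 convention, never read from input
        hits = np.flatnonzero(a[n] == 2 * h)
        w_bar = int(hits[0]) if hits.size == 1 else None
        return cls(n=n, h=h, a=a, w_bar=w_bar)


def composition_multiset(U: StringMultiset | Iterable[str]) -> CompositionMultiset:
    """Build M(U), the multiset union of all prefix and suffix compositions.

    The result contains 2nh compositions counted with multiplicity, stored
    densely; ``a[0, 0]`` is set to 2h by convention.
    """
    if not isinstance(U, StringMultiset):
        U = StringMultiset.from_strings(U)
    n, h = U.n, U.h
    a = np.zeros((n + 1, n + 1), dtype=np.int64)
    for t in U:
        for comps in (prefix_compositions(t), suffix_compositions(t)):
            for z, w in comps:
                a[z + w, w] += 1
    return CompositionMultiset.from_grid(n, h, a)


@dataclass(frozen=True)
class AffixFlowGrids:
    """The b/c/s grids derived from an a-grid.

    ``b[l, w]`` counts length-l weight-w affixes whose weight is unchanged at
    length l-1; ``c[l, w]`` counts those whose weight drops; ``s[l, w]`` is
    the row suffix sum sum_{v>=w} a[l, v].  For any grid arising from real
    strings, ``a = b + c`` on each row and ``a[l, w] = b[l+1, w] + c[l+1, w+1]``.
    """

    b: np.ndarray = field(repr=False)
    c: np.ndarray = field(repr=False)
    s: np.ndarray = field(repr=False)


def affix_flow_grids(M: CompositionMultiset) -> AffixFlowGrids:
    """Compute the b/c/s grids from M.

    b and c follow the closed forms
    ``b[l, w] = sum_{v=w}^{l-1} a[l-1, v] - sum_{v=w+1}^{l} a[l, v]`` and
    ``c[l, w] = sum_{v=w}^{l} a[l, v] - sum_{v=w}^{l-1} a[l-1, v]``
    (the recursive sweep of the flow decomposition collapses to these suffix
    sums).  A negative entry proves M is not the composition multiset of any
    string multiset.
    """
    n = M.n
    a = M.a
    s = np.zeros_like(a)
    # s[l, w] = sum_{v >= w} a[l, v]; row l only has mass at v <= l.
    s[:, :] = np.cumsum(a[:, ::-1], axis=1)[:, ::-1]
    b = np.zeros_like(a)
    c = np.zeros_like(a)
    for l in range(1, n + 1):
        for w in range(0, l + 1):
            b[l, w] = s[l - 1, w] - s[l, w + 1] if w + 1 <= n else s[l - 1, w]
            c[l, w] = s[l, w] - s[l - 1, w]
    if (b < 0).any() or (c < 0).any():
        report = ValidationReport(violations=[
            f"negative flow at (l={l}, w={w}): b={int(b[l, w])}, c={int(c[l, w])}"
            for l in range(1, n + 1)
            for w in range(0, l + 1)
            if b[l, w] < 0 or c[l, w] < 0
        ])
        raise InvalidCompositionsError(report)
    return AffixFlowGrids(b=b, c=c, s=s)


@dataclass
class ValidationReport:
    """Outcome of validating a composition multiset; empty violations = pass."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "composition multiset valid"
        return "invalid composition multiset:\n  " + "\n  ".join(self.violations)


def validate_composition_multiset(M: CompositionMultiset) -> ValidationReport:
    """Check every structural invariant of a composition-multiset grid.

    Report-style: returns the full list of violations with (l, w) witnesses
    rather than raising.  Passing requires nonnegative counts, no mass above
    the diagonal (w > l), a[0,0] = 2h, every row l in 1..n summing to 2h, a
    unique inferable common weight, the constant-weight point symmetry
    a[l, w] = a[n-l, w̄-w], and nonnegative b/c flow grids.
    """
    v: list[str] = []
    n, h, a = M.n, M.h, M.a
    if (a < 0).any():
        for l, w in zip(*np.nonzero(a < 0)):
            v.append(f"negative count a[{l},{w}]={int(a[l, w])}")
    for l in range(n + 1):
        for w in range(l + 1, n + 1):
            if a[l, w] != 0:
                v.append(f"impossible composition: a[{l},{w}]={int(a[l, w])} with w>l")
    if a[0, 0] != 2 * h:
        v.append(f"a[0,0]={int(a[0, 0])} != 2h={2 * h}")
    for l in range(1, n + 1):
        row = int(a[l].sum())
        if row != 2 * h:
            v.append(f"row sum at l={l} is {row}, expected 2h={2 * h}")
    if M.w_bar is None:
        v.append(f"no unique common weight: row l={n} is {a[n].tolist()}")
    else:
        w_bar = M.w_bar
        for l in range(n + 1):
            for w in range(w_bar + 1):
                if a[l, w] != a[n - l, w_bar - w]:
                    v.append(
                        f"constant-weight symmetry broken: a[{l},{w}]="
                        f"{int(a[l, w])} != a[{n - l},{w_bar - w}]="
                        f"{int(a[n - l, w_bar - w])}"
                    )
    if not v:
        try:
            affix_flow_grids(M)
        except InvalidCompositionsError as exc:
            v.extend(exc.report.violations)
    return ValidationReport(violations=v)


def require_valid(M: CompositionMultiset) -> None:
    """Fail fast with the full report if M is invalid (eager validation)."""
    report = validate_composition_multiset(M)
    if not report.ok:
        raise InvalidCompositionsError(report)


def canonical_string(t: str) -> str:
    """The lexicographically smaller of a string and its reversal ('0' < '1')."""
    r = reverse_string(t)
    return t if t <= r else r


def canonical_class(U: StringMultiset | Iterable[str]) -> tuple[str, ...]:
    """Canonical form of the reversal-equivalence class of a string multiset.

    Each member is replaced by min(t, reverse(t)) and the result is sorted.
    Two multisets are reversals of each other iff their canonical classes are
    equal, which makes this the operational form of the equivalence relation.
    """
    if isinstance(U, StringMultiset):
        U = U.members
    return tuple(sorted(canonical_string(t) for t in U))
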