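"""Decide unique reconstructibility up to reversal from any solution CWF.

A constant-weight composition multiset M determines its string multiset
uniquely up to reversal iff any (equivalently, every) solution CWF f has
at most two maximal discrepancy intervals between each partner pair
(f_m, f_m*) and at most one between every non-partner pair.  Three or more
partner intervals, or two non-partner intervals, admit a solution-preserving
swap that produces a genuinely different multiset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .cwf import CWF, maximal_intervals, star
from .greedy import algorithm1
from .strings import CompositionMultiset

logger = logging.getLogger("psrecon")

__all__ = ["UniquenessReport", "check_theorem1", "is_unique"]


@dataclass(frozen=True)
class UniquenessReport:
    """Verdict of the uniqueness test.

    ``witnesses`` lists every violating unordered label pair with its
    maximal intervals (all of them, to support diagnostics; the criterion
    itself only needs one).  ``cwf`` is the solution the verdict was
    computed on, when produced by :func:`is_unique`.
    """

    unique: bool
    witnesses: tuple[tuple[int, int, tuple[tuple[int, int], ...]], ...]
    cwf: CWF | None = None

    def __bool__(self) -> bool:
        return self.unique


def check_theorem1(f: CWF) -> UniquenessReport:
    """Test the interval-count conditions on a solution CWF.

    For every unordered pair (m1, m2): partner pairs (m2 = m1*) may have at
    most two maximal intervals, all other pairs at most one.  The diagonal
    m1 = m2 is vacuous (empty discrepancy) and skipped.
    """
    if f.w_bar is None:
        raise ValueError("uniqueness test requires a constant-weight CWF")
    witnesses = []
    for m1 in range(1, 2 * f.h + 1):
        for m2 in range(m1 + 1, 2 * f.h + 1):
            ivs = maximal_intervals(f, m1, m2)
            limit = 2 if m2 == star(m1, f.h) else 1
            if len(ivs) > limit:
                witnesses.append((m1, m2, tuple(ivs)))
    return UniquenessReport(unique=not witnesses, witnesses=tuple(witnesses), cwf=f)


def is_unique(M: CompositionMultiset) -> UniquenessReport:
    """Decide whether M has exactly one compatible multiset up to reversal.

    Obtains one solution CWF via the greedy solver and applies
    :func:`check_theorem1`; the verdict is independent of which solution is
    used.  Invalid M fails fast with the validation report.
    """
    f, _ = algorithm1(M)
    report = check_theorem1(f)
    logger.info(
        "uniqueness: n=%d h=%d -> %s (%d witness pair(s))",
        M.n, M.h, "unique" if report.unique else "not unique", len(report.witnesses),
    )
    return report
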