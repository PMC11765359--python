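"""Greedy O(nh) construction of one CWF solution to a composition multiset.

The grid row l of M partitions the 2h affixes of length l by weight, and the
row suffix sums s[l, w] = sum_{v>=w} a[l, v] are strictly partitioning: for
each k in [h] there is a unique w with s[l, w+1] < k <= s[l, w].  Assigning
that w to the odd label 2k-1 hands the larger weights to the smaller k — the
greedy choice — and filling the even labels by the rotational mirror
f(l, 2k) = w̄ - f(n-l, 2k-1) completes a constant-weight CWF that occupies
every cell (l, w) exactly a[l, w] times, i.e. a solution to M.
"""

from __future__ import annotations

import logging

import numpy as np

from .cwf import CWF, is_solution, strings_of_cwf
from .strings import (
    CompositionMultiset,
    StringMultiset,
    affix_flow_grids,
    require_valid,
)

logger = logging.getLogger("psrecon")

__all__ = ["algorithm1"]


def algorithm1(M: CompositionMultiset) -> tuple[CWF, StringMultiset]:
    """Construct one CWF solution to M and its corresponding string multiset.

    Requires a validated, constant-weight M; invalid input fails fast with
    the validation report.  The returned CWF satisfies ``is_solution(f, M)``
    (asserted) and the returned multiset is ``strings_of_cwf(f)``, so its
    composition multiset equals M.
    """
    require_valid(M)
    n, h, w_bar = M.n, M.h, M.w_bar
    assert w_bar is not None
    s = affix_flow_grids(M).s
    values = np.zeros((n + 1, 2 * h), dtype=np.int64)
    for l in range(1, n + 1):
        # walk w downward; s[l, w] is non-increasing in w, so each k in [h]
        # lands in exactly one slab (s[l, w+1], s[l, w]].
        w = min(l, w_bar)
        for k in range(1, h + 1):
            while w > 0 and s[l, w] < k:
                w -= 1
            values[l, 2 * k - 2] = w
    # even labels are filled purely by the rotational mirror rule
    for l in range(n + 1):
        for k in range(1, h + 1):
            values[l, 2 * k - 1] = w_bar - values[n - l, 2 * k - 2]
    f = CWF(n=n, h=h, values=values, w_bar=w_bar)
    f.validate()
    if not is_solution(f, M):  # guards the reconstruction of the assignment rule
        raise AssertionError("greedy construction failed to solve M")
    logger.info("greedy solver: built solution CWF for n=%d h=%d w_bar=%d", n, h, w_bar)
    return f, strings_of_cwf(f)
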