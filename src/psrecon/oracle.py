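"""Brute-force ground truth and seeded generation of constant-weight fixtures.

The oracle answers "which reversal-equivalence classes are compatible with
this composition multiset?" by enumeration over the finite universe of
constant-weight multisets, entirely independently of the CWF machinery, so
it can cross-check both the uniqueness test and the scan/assembly
enumerator on small instances.
"""

from __future__ import annotations

import itertools
import logging
import random
from math import comb
from typing import Iterator

import numpy as np

from .strings import (
    CompositionMultiset,
    StringMultiset,
    canonical_class,
    composition_multiset,
    prefix_compositions,
    require_valid,
    suffix_compositions,
)

logger = logging.getLogger("psrecon")

__all__ = [
    "enumerate_constant_weight_strings",
    "enumerate_constant_weight_multisets",
    "classify_universe",
    "oracle_reconstruct_all",
    "random_instance",
]

DEFAULT_MAX_MULTISETS = 10**7


def enumerate_constant_weight_strings(n: int, w_bar: int) -> list[str]:
    """All C(n, w̄) binary strings of length n and weight w̄, sorted."""
    if not 0 <= w_bar <= n:
        raise ValueError(f"need 0 <= w_bar <= n, got w_bar={w_bar}, n={n}")
    out = []
    for ones in itertools.combinations(range(n), w_bar):
        bits = ["0"] * n
        for i in ones:
            bits[i] = "1"
        out.append("".join(bits))
    return sorted(out)


def enumerate_constant_weight_multisets(
    n: int, h: int, w_bar: int, max_count: int = DEFAULT_MAX_MULTISETS
) -> Iterator[StringMultiset]:
    """Stream every size-h multiset over the weight-w̄ strings of length n.

    Combinations with repetition in lexicographic order; each multiset
    appears exactly once.  Refuses universes larger than ``max_count``.
    """
    base = enumerate_constant_weight_strings(n, w_bar)
    total = comb(len(base) + h - 1, h)
    if total > max_count:
        raise ValueError(f"universe has {total} multisets, cap is {max_count}")
    for combo in itertools.combinations_with_replacement(base, h):
        yield StringMultiset.from_strings(combo)


def _affix_grid_vector(t: str, n: int) -> np.ndarray:
    """The flattened a-grid contribution of a single string (without a[0,0])."""
    a = np.zeros((n + 1, n + 1), dtype=np.int64)
    for z, w in prefix_compositions(t):
        a[z + w, w] += 1
    for z, w in suffix_compositions(t):
        a[z + w, w] += 1
    return a.ravel()


def classify_universe(
    n: int, h: int, w_bar: int, max_count: int = DEFAULT_MAX_MULTISETS
) -> dict[bytes, list[tuple[str, ...]]]:
    """Group a full universe of multisets by their composition multiset.

    Returns a map from the serialized a-grid (the CompositionMultiset key)
    to the sorted list of distinct canonical classes sharing it.  This is
    the exhaustive ground truth used to check completeness and soundness of
    the reconstruction on small (n, h, w̄).
    """
    grouped: dict[bytes, set[tuple[str, ...]]] = {}
    for U in enumerate_constant_weight_multisets(n, h, w_bar, max_count=max_count):
        key = composition_multiset(U).key()
        grouped.setdefault(key, set()).add(canonical_class(U))
    return {key: sorted(classes) for key, classes in grouped.items()}


def oracle_reconstruct_all(
    M: CompositionMultiset, max_nodes: int = DEFAULT_MAX_MULTISETS
) -> list[tuple[str, ...]]:
    """All canonical classes compatible with M, by direct enumeration.

    Builds candidate multisets string by string in nondecreasing order over
    the weight-w̄ universe, pruning any partial multiset whose composition
    grid is not componentwise dominated by M's (adding strings only adds
    counts, so domination is necessary for every extension).  The pruning
    is a pure feasibility cut: the result is identical to scoring the full
    enumeration, with no dependence on the CWF machinery being checked.
    """
    require_valid(M)
    n, h = M.n, M.h
    if M.w_bar is None:
        raise ValueError("oracle requires a constant-weight composition multiset")
    base = enumerate_constant_weight_strings(n, M.w_bar)
    vectors = [_affix_grid_vector(t, n) for t in base]
    target = np.array(M.a, dtype=np.int64).ravel()
    target[0] = 0  # a[0,0] is a convention, not an observed affix
    classes: set[tuple[str, ...]] = set()
    nodes = 0

    def rec(start: int, depth: int, acc: np.ndarray, chosen: list[str]) -> None:
        nonlocal nodes
        nodes += 1
        if nodes > max_nodes:
            raise ValueError(f"oracle search exceeded {max_nodes} nodes")
        if depth == h:
            if np.array_equal(acc, target):
                classes.add(canonical_class(chosen))
            return
        for i in range(start, len(base)):
            new = acc + vectors[i]
            if (new <= target).all():
                chosen.append(base[i])
                rec(i, depth + 1, new, chosen)
                chosen.pop()

    rec(0, 0, np.zeros_like(target), [])
    logger.info("oracle: n=%d h=%d -> %d class(es) (%d nodes)", n, h, len(classes), nodes)
    return sorted(classes)


def random_instance(
    n: int, h: int, w_bar: int, seed: int | random.Random
) -> StringMultiset:
    """h independent uniform weight-w̄ strings of length n, reproducibly.

    Each string places its w̄ ones on a uniformly drawn position subset
    (seeded partial Fisher-Yates via ``random.Random.sample``, a documented
    stable stream, so fixtures are portable across platforms).
    """
    if not 0 <= w_bar <= n:
        raise ValueError(f"need 0 <= w_bar <= n, got w_bar={w_bar}, n={n}")
    if h < 1:
        raise ValueError("need h >= 1")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    strings = []
    for _ in range(h):
        bits = ["0"] * n
        for i in rng.sample(range(n), w_bar):
            bits[i] = "1"
        strings.append("".join(bits))
    return StringMultiset.from_strings(strings)
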