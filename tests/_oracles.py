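"""Independent brute-force oracles used by the test suite.

These deliberately re-derive model behaviour by direct rule application or
exhaustive enumeration, staying independent of the library's optimised
code paths.
"""

from fractions import Fraction
from itertools import permutations, product

import numpy as np

from forgetsim import SURVIVED


def brute_force_full_erasure(v: np.ndarray) -> np.ndarray:
    """O(T^2) literal application of the full-erasure rule."""
    v = np.atleast_2d(np.asarray(v, dtype=float).T).T
    T = v.shape[0]
    erasure = np.full(T, SURVIVED, dtype=np.int64)
    store: list[int] = []
    for t0 in range(T):
        new = v[t0]
        still = []
        for j in store:
            if np.all(v[j] < new):
                erasure[j] = t0 + 1
            else:
                still.append(j)
        store = still + [t0]
    return erasure


def brute_force_single_erasure(v: np.ndarray) -> np.ndarray:
    """Literal application of the single-erasure rule (scalar valence)."""
    v = np.asarray(v, dtype=float).ravel()
    erasure = np.full(v.size, SURVIVED, dtype=np.int64)
    store: list[int] = []
    for t0 in range(v.size):
        if store:
            jmin = min(store, key=lambda j: v[j])
            if v[t0] > v[jmin]:
                erasure[jmin] = t0 + 1
                store.remove(jmin)
        store.append(t0)
    return erasure


def retention_by_enumeration(n: int, t: int) -> Fraction:
    """Exact survival probability at lag ``t`` by exhaustive rank enumeration.

    The first of ``t + 1`` items survives iff no later item out-ranks it in
    every one of the ``n`` independent dimensions; all joint rank
    configurations (one permutation per dimension) are equally likely.
    """
    m = t + 1
    total = 0
    hits = 0
    for ranks in product(permutations(range(m)), repeat=n):
        total += 1
        dominated = any(
            all(ranks[d][j] > ranks[d][0] for d in range(n)) for j in range(1, m)
        )
        if not dominated:
            hits += 1
    return Fraction(hits, total)


def is_linear_extension(order: np.ndarray, items: np.ndarray) -> bool:
    """Check that every strict dominator precedes the items it dominates."""
    items = np.asarray(items, dtype=float)
    ordered = items[np.asarray(order)]
    T = ordered.shape[0]
    for i in range(T):
        for j in range(i + 1, T):
            # a later item must never strictly dominate an earlier one
            if np.all(ordered[j] > ordered[i]):
                return False
    return True
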