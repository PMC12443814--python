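"""Independent brute-force oracles used to certify the metric implementations.

Everything here is written directly from the metric definitions, by
enumeration where feasible, and never calls the package's own algorithms.
"""

from __future__ import annotations

import itertools
from math import log

import numpy as np


def wnodf_brute(w: np.ndarray) -> float:
    """Literal weighted-NODF: sort by totals, score every ordered pair."""
    w = np.asarray(w)

    def pair_score(upper: np.ndarray, lower: np.ndarray, tu: int, tv: int) -> float:
        if tv >= tu:
            return 0.0
        filled = [k for k in range(len(lower)) if lower[k] > 0]
        if not filled:
            return 0.0
        less = sum(1 for k in filled if lower[k] < upper[k])
        return 100.0 * less / len(filled)

    def axis(mat: np.ndarray) -> float:
        totals = mat.sum(axis=1)
        order = sorted(range(mat.shape[0]), key=lambda i: (-totals[i], i))
        total = 0.0
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                u, v = order[a], order[b]
                total += pair_score(mat[u], mat[v], totals[u], totals[v])
        return total

    n_r, n_c = w.shape
    pairs = n_r * (n_r - 1) / 2 + n_c * (n_c - 1) / 2
    return (axis(w) + axis(w.T)) / pairs


def matrices_with_marginals(row_totals, col_totals):
    """Yield every nonnegative integer matrix with the given marginals."""
    row_totals = list(row_totals)
    col_totals = list(col_totals)

    def rows(remaining_cols, row_idx):
        if row_idx == len(row_totals):
            if all(c == 0 for c in remaining_cols):
                yield []
            return
        target = row_totals[row_idx]
        for combo in compositions(target, len(remaining_cols)):
            if all(c <= rc for c, rc in zip(combo, remaining_cols)):
                rest = [rc - c for rc, c in zip(remaining_cols, combo)]
                for tail in rows(rest, row_idx + 1):
                    yield [list(combo)] + tail

    yield from (np.array(m) for m in rows(col_totals, 0))


def compositions(total: int, parts: int):
    """All ways to write ``total`` as an ordered sum of ``parts`` >= 0 terms."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first,) + rest


def shannon(w: np.ndarray) -> float:
    p = w[w > 0] / w.sum()
    return float(-(p * np.log(p)).sum())


def entropy_extremes_exhaustive(row_totals, col_totals) -> tuple[float, float]:
    """(min, max) Shannon entropy over all matrices with the marginals."""
    values = [shannon(m) for m in matrices_with_marginals(row_totals, col_totals)]
    return min(values), max(values)


def dmin_exhaustive(t: int, avail_totals: np.ndarray, m: int) -> float:
    """Minimum KL divergence over all integer allocations of t events."""
    q = np.asarray(avail_totals, dtype=float) / m
    best = np.inf
    for combo in compositions(t, len(q)):
        a = np.array(combo, dtype=float)
        nz = a > 0
        p = a[nz] / t
        d = float((p * np.log(p / q[nz])).sum())
        best = min(best, d)
    return best


def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def barber_q_brute(w: np.ndarray) -> float:
    """Exact max of Barber bipartite modularity by exhaustive search.

    Enumerates set partitions of the rows; given row modules, each column's
    optimal module is chosen independently (its best row-module, or a
    singleton if every choice is negative) -- which is exact for bipartite
    modularity since column terms are additive.
    """
    w = np.asarray(w, dtype=float)
    m = w.sum()
    b = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / m
    best = -np.inf
    for part in set_partitions(range(w.shape[0])):
        total = 0.0
        for j in range(w.shape[1]):
            gains = [b[rows, j].sum() for rows in part]
            total += max(0.0, max(gains))
        best = max(best, total / m)
    return best


def hypergeom_2x2_pmf(r0: int, r1: int, c0: int, c1: int) -> dict[int, float]:
    """Exact pmf of the top-left cell of a 2x2 table with fixed marginals."""
    from math import comb

    m = r0 + r1
    assert m == c0 + c1
    lo = max(0, c0 - r1)
    hi = min(r0, c0)
    weights = {k: comb(r0, k) * comb(r1, c0 - k) for k in range(lo, hi + 1)}
    z = sum(weights.values())
    return {k: v / z for k, v in weights.items()}
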