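"""Independent reference implementations used as test oracles.

Deliberately naive (quadratic / exhaustive) and kept separate from the
package code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_cpg_scan(text: str) -> list[int]:
    """Exhaustive substring scan for CG dinucleotides."""
    return [i for i in range(len(text) - 1) if text[i : i + 2] == "CG"]


def gotoh_global_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Full three-matrix affine-gap global alignment DP (no traceback).

    A gap of length k scores gap_open + (k-1)*gap_extend.
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (a consumed)
    Iy = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(
                M[i - 1, j] + gap_open,
                Ix[i - 1, j] + gap_extend,
                Iy[i - 1, j] + gap_open,
            )
            Iy[i, j] = max(
                M[i, j - 1] + gap_open,
                Iy[i, j - 1] + gap_extend,
                Ix[i, j - 1] + gap_open,
            )
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def quadratic_bh(pvals) -> list[float]:
    """Textbook Benjamini-Hochberg step-up, O(n^2)."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank, i in enumerate(order, start=1):
        adj[i] = min(1.0, p[i] * m / rank)
    # enforce monotonicity from the largest p downwards
    for k in range(m - 2, -1, -1):
        i, j = order[k], order[k + 1]
        adj[i] = min(adj[i], adj[j])
    return adj


def contiguous_partitions(n: int):
    """All partitions of range(n) into contiguous blocks."""
    if n == 0:
        yield []
        return
    for cuts in itertools.product([0, 1], repeat=n - 1):
        blocks = []
        start = 0
        for i, cut in enumerate(cuts, start=1):
            if cut:
                blocks.append(tuple(range(start, i)))
                start = i
        blocks.append(tuple(range(start, n)))
        yield blocks


def exhaustive_unit_pairing(n_a: int, n_b: int, edges: set[tuple[int, int]]):
    """Reference unit pairing by exhaustive search over merge partitions.

    Units are indexed 0..n-1 per side; `edges` are (unit_a, unit_b)
    orthologous-site links.  Among all pairs of contiguous partitions of
    each side admitting a consistent block matching (every edge internal
    to exactly one matched block pair, each matched pair having >=1
    edge, unmatched blocks edge-free), return the matching with the
    maximum number of matched pairs as a set of
    (frozenset(a_units), frozenset(b_units)).

    Edge-free units are excluded from pairing by definition, so they are
    dropped before enumeration; merged groups are contiguous in the
    ordering of the remaining (edge-bearing) units when site pairs come
    from a (monotone) alignment, which the caller must guarantee.
    """
    keep_a = sorted({x for x, _ in edges})
    keep_b = sorted({y for _, y in edges})
    red_a = {u: i for i, u in enumerate(keep_a)}
    red_b = {u: i for i, u in enumerate(keep_b)}
    edges = {(red_a[x], red_b[y]) for x, y in edges}
    n_a, n_b = len(keep_a), len(keep_b)

    best: set | None = None
    best_key = (-1, 0)
    for part_a in contiguous_partitions(n_a):
        block_of_a = {u: k for k, blk in enumerate(part_a) for u in blk}
        for part_b in contiguous_partitions(n_b):
            block_of_b = {u: k for k, blk in enumerate(part_b) for u in blk}
            a_to_b: dict[int, set[int]] = {}
            b_to_a: dict[int, set[int]] = {}
            for x, y in edges:
                a_to_b.setdefault(block_of_a[x], set()).add(block_of_b[y])
                b_to_a.setdefault(block_of_b[y], set()).add(block_of_a[x])
            if any(len(v) != 1 for v in a_to_b.values()):
                continue
            if any(len(v) != 1 for v in b_to_a.values()):
                continue
            # unmatched blocks must be edge-free (they are, by construction)
            matched = {
                (
                    frozenset(keep_a[u] for u in part_a[ka]),
                    frozenset(keep_b[u] for u in part_b[next(iter(kb))]),
                )
                for ka, kb in a_to_b.items()
            }
            size = sum(len(a) + len(b) for a, b in matched)
            key = (len(matched), -size)
            if key > best_key:
                best_key = key
                best = matched
    assert best is not None
    return best


def explicit_spearman_rho(x, y) -> float:
    """Spearman rho from first principles: average ranks + Pearson."""

    def ranks(v):
        v = list(map(float, v))
        out = [0.0] * len(v)
        for i, vi in enumerate(v):
            smaller = sum(1 for u in v if u < vi)
            equal = sum(1 for u in v if u == vi)
            out[i] = smaller + (equal + 1) / 2
        return out

    rx, ry = ranks(x), ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den
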