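"""Independent brute-force oracles used only by the test suite.

Each oracle is written from first principles (agglomeration recursion,
normal equations, exact combinatorial enumeration, two-pass correlation)
and never calls the code path it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_ward_cophenetic(distance: np.ndarray) -> tuple[list[float], np.ndarray]:
    """Ward agglomeration by direct Lance-Williams recursion.

    Returns the sorted merge heights and the cophenetic matrix built by
    recording, for every leaf pair, the height of the merge at which the two
    leaves first share a cluster.
    """
    n = len(distance)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(distance[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    coph = np.zeros((n, n))
    heights: list[float] = []
    next_id = n
    while len(members) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        for a in members[i]:
            for b in members[j]:
                coph[a, b] = coph[b, a] = h
        ni, nj = len(members[i]), len(members[j])
        merged = members[i] + members[j]
        d_ij = dist.pop((i, j))
        new_dist = {}
        for k in members:
            if k in (i, j):
                continue
            nk = len(members[k])
            d_ik = dist.pop((min(i, k), max(i, k)))
            d_jk = dist.pop((min(j, k), max(j, k)))
            d_new = math.sqrt(
                ((ni + nk) * d_ik**2 + (nj + nk) * d_jk**2 - nk * d_ij**2)
                / (ni + nj + nk)
            )
            new_dist[(k, next_id)] = d_new
        del members[i], members[j]
        members[next_id] = merged
        dist.update(new_dist)
        next_id += 1
    return heights, coph


def tree_walk_cophenetic(linkage: np.ndarray) -> np.ndarray:
    """Cophenetic matrix from walking a merge tree's (n-1) agglomerations."""
    n = linkage.shape[0] + 1
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    for step, (left, right, height, _) in enumerate(linkage):
        li, ri = int(left), int(right)
        for a in members[li]:
            for b in members[ri]:
                coph[a, b] = coph[b, a] = height
        members[n + step] = members.pop(li) + members.pop(ri)
    return coph


def normal_equations_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients (intercept first) via the normal equations."""
    design = np.hstack([np.ones((len(X), 1)), X])
    return np.linalg.solve(design.T @ design, design.T @ y)


def hypergeom_upper_tail(k: int, n_total: int, big_k: int, small_n: int) -> float:
    """P(overlap >= k) by exact enumeration of combination counts."""
    total = math.comb(n_total, small_n)
    acc = 0
    for x in range(max(k, 0), min(big_k, small_n) + 1):
        if small_n - x <= n_total - big_k:
            acc += math.comb(big_k, x) * math.comb(n_total - big_k, small_n - x)
    return acc / total


def two_pass_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum()))
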