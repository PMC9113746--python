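"""Independent brute-force oracles used to validate the implementation paths.

Each oracle is deliberately naive (enumeration, closed-form tails,
step-by-step agglomeration, literal step-up) and shares no code with the
functions it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def bh_step_up(p_values) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up: sort, scale by n/rank, cummin."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adjusted[idx] = running
    return adjusted


def hypergeom_tail(overlap: int, universe: int, category: int, selected: int) -> float:
    """P(X >= overlap) by summing closed-form hypergeometric terms."""
    total = 0
    hi = min(category, selected)
    for k in range(overlap, hi + 1):
        total += comb(category, k) * comb(universe - category, selected - k)
    return total / comb(universe, selected)


def hypergeom_tail_enumerated(
    overlap: int, universe_genes: list, category_genes: set, selected_size: int
) -> float:
    """P(X >= overlap) by enumerating every possible selection (tiny n only)."""
    hits = 0
    total = 0
    for combo in combinations(universe_genes, selected_size):
        total += 1
        if len(category_genes.intersection(combo)) >= overlap:
            hits += 1
    return hits / total


def agglomerate(points: np.ndarray, k: int, linkage: str = "complete") -> list[set]:
    """Naive agglomerative clustering via Lance–Williams updates.

    Starts from singleton clusters and repeatedly merges the pair at
    minimal linkage distance until k clusters remain.  Supports complete,
    average and ward linkage on Euclidean distances.
    """
    n = len(points)
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(points[i] - points[j]))
            dist[frozenset((i, j))] = d
    next_id = n
    while len(clusters) > k:
        (ci, cj), dij = min(
            (
                (pair, dist[frozenset(pair)])
                for pair in combinations(sorted(clusters), 2)
            ),
            key=lambda item: item[1],
        )
        ni, nj = len(clusters[ci]), len(clusters[cj])
        merged = clusters.pop(ci) | clusters.pop(cj)
        new_dist = {}
        for ck, members in clusters.items():
            nk = len(members)
            dki = dist[frozenset((ck, ci))]
            dkj = dist[frozenset((ck, cj))]
            if linkage == "complete":
                d = max(dki, dkj)
            elif linkage == "average":
                d = (ni * dki + nj * dkj) / (ni + nj)
            elif linkage == "ward":
                d = np.sqrt(
                    (
                        (nk + ni) * dki**2
                        + (nk + nj) * dkj**2
                        - nk * dij**2
                    )
                    / (nk + ni + nj)
                )
            else:
                raise ValueError(linkage)
            new_dist[frozenset((ck, next_id))] = float(d)
        clusters[next_id] = merged
        dist.update(new_dist)
        next_id += 1
    return [set(members) for members in clusters.values()]


def partition_of_labels(labels) -> set[frozenset]:
    """Turn a label vector into a relabeling-invariant partition."""
    groups: dict = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(idx)
    return {frozenset(g) for g in groups.values()}


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² from the normal equations, written out."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    sst = ((y - ybar) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / sst
    return slope, intercept, r2
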