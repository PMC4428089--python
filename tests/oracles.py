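"""Independent brute-force oracles used only by the test suite.

Deliberately slow, loop-based implementations that share no code with
the package: chord statistics by explicit line walking, Mann-Whitney by
explicit enumeration of group labelings, Spearman by rank-then-Pearson
plus full permutation of one variable.
"""

from __future__ import annotations

import itertools
from statistics import median

import numpy as np


def chord_median_bruteforce(grid: np.ndarray, axis: int, spacing: float):
    """Median chord along an axis by walking every line, python loops."""
    moved = np.moveaxis(grid, axis, 2)
    chords = []
    for i in range(moved.shape[0]):
        for j in range(moved.shape[1]):
            count = 0
            for k in range(moved.shape[2]):
                if moved[i, j, k]:
                    count += 1
            if count:
                chords.append(count * spacing)
    if not chords:
        raise ValueError("empty grid")
    return median(chords)


def mann_whitney_u_bruteforce(x, y) -> float:
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney_p_bruteforce(x, y) -> float:
    """Two-sided exact p by enumerating every C(n1+n2, n1) labeling."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = mann_whitney_u_bruteforce(x, y)
    count = total = 0
    idx = range(len(pooled))
    for subset in itertools.combinations(idx, n1):
        chosen = set(subset)
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in idx if i not in chosen]
        u = mann_whitney_u_bruteforce(xs, ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def ranks_average(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_r_bruteforce(x, y) -> float:
    return pearson(ranks_average(list(x)), ranks_average(list(y)))


def spearman_p_bruteforce(x, y) -> float:
    """Exact two-sided permutation p over all orderings of y."""
    r_obs = abs(spearman_r_bruteforce(x, y))
    count = total = 0
    for perm in itertools.permutations(list(y)):
        total += 1
        if abs(spearman_r_bruteforce(x, perm)) >= r_obs - 1e-12:
            count += 1
    return count / total
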