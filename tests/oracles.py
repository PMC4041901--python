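"""Independent brute-force oracles, written before the implementations they check.

These deliberately use naive algorithms (explicit flood fill, exhaustive pair
counting, direct summation) so they share no code path with the package.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> List[Set[Tuple[int, int]]]:
    """Connected components of a boolean grid by explicit BFS flood fill."""
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise ValueError(connectivity)
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    components: List[Set[Tuple[int, int]]] = []
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp: Set[Tuple[int, int]] = set()
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            components.append(comp)
    return components


def filter_components_oracle(
    mask: np.ndarray,
    pixel_spacing: Tuple[float, float],
    min_area_mm2: float,
    connectivity: int,
) -> FrozenSet[FrozenSet[Tuple[int, int]]]:
    """Retained component set under the minimum-area rule, via flood fill."""
    area = pixel_spacing[0] * pixel_spacing[1]
    return frozenset(
        frozenset(c)
        for c in flood_fill_components(mask, connectivity)
        if len(c) * area >= min_area_mm2
    )


def auc_pair_counting(scores, truth) -> float:
    """AUC by exhaustive enumeration of between-class pairs, ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pos = scores[truth]
    neg = scores[~truth]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def delong_oracle(scores_a, scores_b, truth):
    """DeLong z-statistic by direct summation over structural components."""
    truth = np.asarray(truth, dtype=bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    def components(s):
        pos, neg = s[truth], s[~truth]
        m, n = len(pos), len(neg)
        v10 = np.array([sum(psi(x, y) for y in neg) / n for x in pos])
        v01 = np.array([sum(psi(x, y) for x in pos) / m for y in neg])
        return v10, v01, v10.mean()

    v10a, v01a, auc_a = components(a)
    v10b, v01b, auc_b = components(b)
    m, n = len(v10a), len(v01a)

    def cov(u, v):
        return float(((u - u.mean()) * (v - v.mean())).sum() / (len(u) - 1))

    var = (
        cov(v10a, v10a) / m + cov(v01a, v01a) / n
        + cov(v10b, v10b) / m + cov(v01b, v01b) / n
        - 2 * (cov(v10a, v10b) / m + cov(v01a, v01b) / n)
    )
    z = (auc_a - auc_b) / np.sqrt(var)
    return auc_a, auc_b, z


def cochran_q_oracle(x: np.ndarray) -> float:
    """Cochran's Q by its textbook definition, summation written out."""
    x = np.asarray(x, dtype=int)
    n, k = x.shape
    col_totals = [sum(x[i][j] for i in range(n)) for j in range(k)]
    row_totals = [sum(x[i][j] for j in range(k)) for i in range(n)]
    grand = sum(col_totals)
    num = (k - 1) * sum((c - grand / k) ** 2 for c in col_totals) * k
    den = k * grand - sum(r * r for r in row_totals)
    return num / den
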