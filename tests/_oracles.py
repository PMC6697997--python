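"""Independent brute-force oracles used only by the test suite.

Everything here is written as plain double loops straight from the
defining formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ngtdm_brute_force(
    values: np.ndarray,
    valid: np.ndarray,
    distance: int = 1,
    policy: str = "strict-interior",
) -> tuple[dict[int, float], dict[int, float], int]:
    """NGTDM s(i), p(i), n by explicit per-pixel loops."""
    h, w = values.shape
    d = distance
    s: dict[int, float] = {}
    counts: dict[int, int] = {}
    n = 0
    for r in range(h):
        for c in range(w):
            if not valid[r, c]:
                continue
            neigh = []
            full = True
            for dr in range(-d, d + 1):
                for dc in range(-d, d + 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and valid[rr, cc]:
                        neigh.append(int(values[rr, cc]))
                    else:
                        full = False
            if policy == "strict-interior":
                if not full:
                    continue
            else:
                if len(neigh) == 0:
                    continue
            i = int(values[r, c])
            a_bar = sum(neigh) / len(neigh)
            s[i] = s.get(i, 0.0) + abs(i - a_bar)
            counts[i] = counts.get(i, 0) + 1
            n += 1
    p = {i: counts[i] / n for i in counts} if n else {}
    for i in p:
        s.setdefault(i, 0.0)
    return s, p, n


def features_brute_force(
    s: dict[int, float], p: dict[int, float], n: int, epsilon: float = 1e-8
) -> tuple[float, float, float]:
    """(coarseness, contrast, busyness) from NGTDM components."""
    levels = sorted(i for i in p if p[i] > 0)
    ng = len(levels)
    ps_sum = sum(p[i] * s.get(i, 0.0) for i in levels)
    coarse = 1.0 / (epsilon + ps_sum)
    if ng <= 1:
        contr = 0.0
    else:
        disp = 0.0
        for i in levels:
            for j in levels:
                disp += p[i] * p[j] * (i - j) ** 2
        disp /= ng * (ng - 1)
        contr = disp * sum(s.get(i, 0.0) for i in levels) / n
    denom = 0.0
    for i in levels:
        for j in levels:
            denom += abs(i * p[i] - j * p[j])
    busy = 0.0 if denom == 0.0 else ps_sum / denom
    return coarse, contr, busy


def auc_pair_count(scores, malignant) -> float:
    """AUC as the Mann-Whitney pair count (ties count half) over every
    benign/malignant pair."""
    pos = [s for s, m in zip(scores, malignant) if m]
    neg = [s for s, m in zip(scores, malignant) if not m]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def ranksum_exact_enumeration(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating every assignment of the
    pooled average ranks to group a (feasible for small samples only)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    order = sorted(range(len(pooled)), key=lambda k: pooled[k])
    ranks = [0.0] * len(pooled)
    k = 0
    while k < len(pooled):
        j = k
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[k]]:
            j += 1
        avg = (k + j) / 2 + 1
        for t in range(k, j + 1):
            ranks[order[t]] = avg
        k = j + 1
    w_obs = sum(ranks[:n_a])
    sums = [sum(ranks[i] for i in combo)
            for combo in itertools.combinations(range(len(pooled)), n_a)]
    n_total = len(sums)
    p_le = sum(1 for w in sums if w <= w_obs + 1e-9) / n_total
    p_ge = sum(1 for w in sums if w >= w_obs - 1e-9) / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))
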