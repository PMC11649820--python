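"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the production paths: the staging
oracle enumerates look-back windows with plain Python loops and datetime
arithmetic, and the agreement oracle evaluates the coefficient definition
by direct double summation.
"""

from __future__ import annotations

import statistics
from datetime import timedelta
from math import comb


def oracle_stage(times: list, values: list[float], i: int,
                 *, high_c1_enabled: bool = True) -> int:
    """Stage the i-th result of one patient's series by window enumeration."""
    t, c1 = times[i], values[i]
    rv1_window, rv2_window, last48 = [], [], []
    for tj, vj in zip(times, values):
        if tj >= t:
            continue
        gap = t - tj
        if gap < timedelta(days=7):
            rv1_window.append(vj)
        if timedelta(days=7) <= gap <= timedelta(days=365):
            rv2_window.append(vj)
        if gap < timedelta(hours=48):
            last48.append(vj)

    ratios = []
    if rv1_window:
        ratios.append(c1 / min(rv1_window))
    if rv2_window:
        ratios.append(c1 / statistics.median(rv2_window))
    ratio = max(ratios) if ratios else None

    if ratio is not None and ratio >= 3.0:
        return 3
    if high_c1_enabled and ratio is not None and ratio >= 1.5 and c1 >= 354.0:
        return 3
    if ratio is not None and ratio >= 2.0:
        return 2
    if ratio is not None and ratio >= 1.5:
        return 1
    if last48 and c1 - min(last48) > 26.0:
        return 1
    return 0


def oracle_weights(q: int) -> list[list[float]]:
    return [[1.0 - comb(abs(k - l) + 1, 2) / comb(q, 2) for l in range(q)]
            for k in range(q)]


def oracle_ac1(counts, weights=None) -> float:
    """Weighted AC1 by direct summation over the matrix definition."""
    q = len(counts)
    if weights is None:
        weights = oracle_weights(q)
    n = sum(sum(row) for row in counts)
    pa = 0.0
    for k in range(q):
        for l in range(q):
            pa += weights[k][l] * counts[k][l] / n

    pi = []
    for k in range(q):
        row = sum(counts[k]) / n
        col = sum(counts[j][k] for j in range(q)) / n
        pi.append((row + col) / 2.0)

    tw = sum(sum(row) for row in weights)
    pe = tw / (q * (q - 1)) * sum(p * (1 - p) for p in pi)
    return (pa - pe) / (1 - pe)
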