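"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written as plain Python loops over scalars, kept
deliberately separate from the vectorized implementations they check.
"""

from __future__ import annotations

import cmath
import math


def sign_sum_loop(xs) -> int:
    total = 0
    for v in xs:
        if v > 0:
            total += 1
        elif v < 0:
            total -= 1
    return total


def count_peaks_loop(xs) -> int:
    count = 0
    for i in range(1, len(xs) - 1):
        if xs[i] > xs[i - 1] and xs[i] > xs[i + 1]:
            count += 1
    return count


def principal_frequency_loop(xs, rate: float) -> float:
    """Largest-magnitude non-DC DFT bin by direct summation."""
    n = len(xs)
    best_mag, best_freq = -1.0, 0.0
    dc = abs(sum(xs))
    for k in range(1, n // 2 + 1):
        acc = 0j
        for t, v in enumerate(xs):
            acc += v * cmath.exp(-2j * cmath.pi * k * t / n)
        mag = abs(acc)
        if mag > best_mag:
            best_mag = mag
            best_freq = k * rate / n
    if best_mag <= 1e-9 * (dc + 1.0):
        return 0.0
    return best_freq


def correlation_loop(ys, zs) -> float:
    n = len(ys)
    my = sum(ys) / n
    mz = sum(zs) / n
    num = sum((y - my) * (z - mz) for y, z in zip(ys, zs))
    vy = sum((y - my) ** 2 for y in ys)
    vz = sum((z - mz) ** 2 for z in zs)
    if vy == 0 or vz == 0:
        return 0.0
    return num / math.sqrt(vy * vz)


def mean_loop(xs) -> float:
    return sum(xs) / len(xs)


def var_loop(xs) -> float:
    m = mean_loop(xs)
    return sum((v - m) ** 2 for v in xs) / len(xs)


def range_loop(xs) -> float:
    return max(xs) - min(xs)


def resultant_loop(ax, ay, az):
    return [math.sqrt(x * x + y * y + z * z) for x, y, z in zip(ax, ay, az)]


def feature_vector_loop(ka, angvel, acc, rate: float) -> list[float]:
    """The 20 features recomputed feature-by-feature with loops."""
    av_x = [row[0] for row in angvel]
    av_y = [row[1] for row in angvel]
    av_z = [row[2] for row in angvel]
    ac_x = [row[0] for row in acc]
    ac_y = [row[1] for row in acc]
    ac_z = [row[2] for row in acc]
    res = resultant_loop(ac_x, ac_y, ac_z)
    return [
        mean_loop(ka),
        mean_loop(av_x),
        mean_loop(av_y),
        mean_loop(ac_y),
        mean_loop(ac_z),
        var_loop(ka),
        range_loop(ka),
        range_loop(av_x),
        min(ka),
        min(av_y),
        max(ac_y),
        sign_sum_loop(av_x),
        sign_sum_loop(av_y),
        sign_sum_loop(av_z),
        sign_sum_loop(ac_x),
        sign_sum_loop(ac_y),
        sign_sum_loop(ac_z),
        count_peaks_loop(res),
        principal_frequency_loop(av_y, rate),
        correlation_loop(ac_z, ac_y),
    ]


def confusion_loop(true, pred, class_order):
    k = len(class_order)
    idx = {c: i for i, c in enumerate(class_order)}
    counts = [[0] * k for _ in range(k)]
    for t, p in zip(true, pred):
        counts[idx[t]][idx[p]] += 1
    return counts


def binary_metrics_loop(tp: float, fn: float, fp: float, tn: float) -> dict:
    """One-vs-rest metrics by direct scalar arithmetic (0 when undefined)."""

    def div(a, b):
        return a / b if b != 0 else 0.0

    sens = div(tp, tp + fn)
    spec = div(tn, tn + fp)
    prec = div(tp, tp + fp)
    fs = div(2 * prec * sens, prec + sens)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = div(tp * tn - fp * fn, mcc_den)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f_score": fs,
        "mcc": mcc,
    }


def best_split_loop(X, y):
    """Exhaustive information-gain search over all midpoint thresholds.

    Returns (feature, threshold, gain) maximizing gain, ties toward
    lower feature then lower threshold; children must get >= 2 rows.
    """

    def entropy(labels):
        n = len(labels)
        if n == 0:
            return 0.0
        h = 0.0
        for c in set(labels):
            p = labels.count(c) / n
            h -= p * math.log(p)
        return h

    n = len(y)
    h_parent = entropy(list(y))
    best = None
    for f in range(len(X[0])):
        vals = sorted(set(row[f] for row in X))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left = [y[i] for i in range(n) if X[i][f] <= thr]
            right = [y[i] for i in range(n) if X[i][f] > thr]
            if len(left) < 2 or len(right) < 2:
                continue
            gain = h_parent - (
                len(left) * entropy(left) + len(right) * entropy(right)
            ) / n
            if best is None or gain > best[2] + 1e-12:
                best = (f, thr, gain)
    return best
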