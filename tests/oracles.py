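"""Independent straight-from-definition oracles used by the test suite.

Everything here is written directly from the statistical and kinematic
definitions with plain Python loops (or explicit normal equations), kept
deliberately separate from the library's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math
from math import factorial

import numpy as np


# -- feature oracles ---------------------------------------------------------

def strokes_bruteforce(pressure) -> list[tuple[int, int]]:
    """Maximal runs of pressure > 0, by row scan."""
    runs, start = [], None
    for i, p in enumerate(pressure):
        if p > 0 and start is None:
            start = i
        elif p <= 0 and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(pressure) - 1))
    return runs


def speeds_bruteforce(t, x, y, strokes) -> list[float]:
    out = []
    for s, e in strokes:
        for i in range(s, e):
            d = math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
            out.append(d / (t[i + 1] - t[i]))
    return out


def mean_sd_cv(values) -> tuple[float, float, float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    return mean, sd, (sd / mean if mean != 0 else 0.0)


def median_bruteforce(values) -> float:
    v = sorted(values)
    n = len(v)
    mid = n // 2
    return v[mid] if n % 2 else 0.5 * (v[mid - 1] + v[mid])


def mad_bruteforce(values) -> float:
    med = median_bruteforce(values)
    return median_bruteforce([abs(v - med) for v in values])


def pauses_bruteforce(t, x, y, strokes, radius=0.25, min_duration=0.1):
    """O(n^2) anchor-rule scan: every window checked sample by sample."""
    within = []
    for s, e in strokes:
        i = s
        while i <= e:
            j = i
            for k in range(i + 1, e + 1):
                if math.hypot(x[k] - x[i], y[k] - y[i]) > radius:
                    break
                j = k
            if t[j] - t[i] > min_duration:
                within.append(("within_stroke", t[i], t[j]))
                i = j + 1
            else:
                i += 1
    between = [("between_strokes", t[e1], t[s2])
               for (_, e1), (s2, _) in zip(strokes[:-1], strokes[1:])]
    return sorted(within + between, key=lambda p: p[1])


def pause_ratio_bruteforce(t, strokes, pauses) -> float:
    total_pause = sum(e - s for _, s, e in pauses)
    within = sum(e - s for kind, s, e in pauses if kind == "within_stroke")
    stroke_time = sum(t[e] - t[s] for s, e in strokes)
    return total_pause / (stroke_time - within)


def features_bruteforce(stream) -> dict[str, float]:
    """All six features straight from their definitions (row loops)."""
    t, x, y = list(stream.t), list(stream.x), list(stream.y)
    strokes = strokes_bruteforce(list(stream.pressure))
    speeds = speeds_bruteforce(t, x, y, strokes)
    mean, _, cv = mean_sd_cv(speeds)
    on_p = [p for s, e in strokes for p in stream.pressure[s:e + 1]]
    on_h = [v for s, e in strokes for v in stream.incl_h[s:e + 1]]
    on_v = [v for s, e in strokes for v in stream.incl_v[s:e + 1]]
    pauses = pauses_bruteforce(t, x, y, strokes)
    return {
        "speed_mean": mean,
        "speed_cv": cv,
        "pressure_mad": mad_bruteforce(on_p),
        "incl_h_sd": mean_sd_cv(on_h)[1],
        "incl_v_sd": mean_sd_cv(on_v)[1],
        "pause_ratio": pause_ratio_bruteforce(t, strokes, pauses),
    }


# -- statistics oracles ------------------------------------------------------

def residualize_normal_equations(v, covariates):
    """Residuals of v on [intercept | covariates] via explicit normal equations."""
    n = len(v)
    X = np.column_stack([np.ones(n), covariates]) if covariates is not None \
        else np.ones((n, 1))
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(v, dtype=float))
    return np.asarray(v, dtype=float) - X @ beta


def pearson_bruteforce(a, b) -> float:
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    num = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
    da = math.sqrt(sum((ai - ma) ** 2 for ai in a))
    db = math.sqrt(sum((bi - mb) ** 2 for bi in b))
    return num / (da * db)


def partial_correlation_bruteforce(x, y, covariates):
    rx = residualize_normal_equations(x, covariates)
    ry = residualize_normal_equations(y, covariates)
    return pearson_bruteforce(list(rx), list(ry))


def bh_bruteforce(pvalues) -> list[float]:
    """Step-up BH directly from the definition: q_(i) = min_{j>=i} m p_(j)/j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        q = min(min(1.0, m * pvalues[order[j - 1]] / j) for j in range(rank, m + 1))
        adjusted[idx] = q
    return adjusted


def pooled_t_bruteforce(a, b) -> tuple[float, int]:
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


# -- Shapley oracle ----------------------------------------------------------

def shapley_bruteforce(predict, x, background) -> tuple[float, list[float]]:
    """Exact interventional Shapley values for one sample by subset loops."""
    x = list(x)
    B = [list(row) for row in background]
    d = len(x)

    def value(subset: frozenset) -> float:
        total = 0.0
        for row in B:
            spliced = [x[i] if i in subset else row[i] for i in range(d)]
            total += float(predict(np.asarray([spliced]))[0])
        return total / len(B)

    phi = []
    others = list(range(d))
    for i in range(d):
        rest = [j for j in others if j != i]
        contrib = 0.0
        for k in range(d):
            for subset in itertools.combinations(rest, k):
                S = frozenset(subset)
                w = factorial(len(S)) * factorial(d - len(S) - 1) / factorial(d)
                contrib += w * (value(S | {i}) - value(S))
        phi.append(contrib)
    return value(frozenset()), phi
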