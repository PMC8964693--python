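"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over Python scalars, deliberately
ignorant of the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def loop_mean(values) -> float:
    total = 0.0
    n = 0
    for v in values:
        total += float(v)
        n += 1
    return total / n


def loop_sample_std(values) -> float:
    vals = [float(v) for v in values]
    m = loop_mean(vals)
    acc = 0.0
    for v in vals:
        acc += (v - m) ** 2
    return math.sqrt(acc / (len(vals) - 1))


def loop_dtr(mins, maxs) -> float:
    ranges = []
    for lo, hi in zip(mins, maxs):
        ranges.append(float(hi) - float(lo))
    return loop_mean(ranges)


def loop_dhw(weekly_values, mmm, weeks=12, threshold=1.0) -> float:
    """DHW at the final week of the sequence."""
    window = list(weekly_values)[-weeks:]
    total = 0.0
    for v in window:
        hot = float(v) - mmm
        if hot >= threshold:
            total += hot
    return total


def loop_tsa_dhw_values(weekly_values, baseline, weeks=12, threshold=1.0):
    """All valid trailing-window accumulated-TSA sums."""
    vals = [float(v) for v in weekly_values]
    out = []
    for end in range(weeks - 1, len(vals)):
        total = 0.0
        for v in vals[end - weeks + 1:end + 1]:
            t = v - baseline
            if t >= threshold:
                total += t
        out.append(total)
    return out


def loop_ssta_counts(weekly_values, week_numbers, years, weekly_clim,
                     threshold=1.0):
    """Anomalous-week count per year; weekly_clim maps week number → mean."""
    counts = {}
    for v, w, y in zip(weekly_values, week_numbers, years):
        if float(v) - weekly_clim[int(w)] >= threshold:
            counts[int(y)] = counts.get(int(y), 0) + 1
    return counts


def exhaustive_best_split(X, y, min_obs=1):
    """Scan every feature and every midpoint; return (sse_after, feature,
    threshold) for the least-squares-optimal single split, or None."""

    def sse(vals):
        if len(vals) == 0:
            return 0.0
        m = loop_mean(vals)
        return sum((v - m) ** 2 for v in vals)

    n, p = X.shape
    best = None
    for j in range(p):
        xs = sorted(set(float(v) for v in X[:, j] if not math.isnan(v)))
        for a, b in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (a + b)
            left = [float(y[i]) for i in range(n) if X[i, j] <= thr]
            right = [float(y[i]) for i in range(n) if X[i, j] > thr]
            if len(left) < min_obs or len(right) < min_obs:
                continue
            total = sse(left) + sse(right)
            if best is None or total < best[0] - 1e-12:
                best = (total, j, thr)
    return best


def brute_partial_dependence(results, X_df, feature, grid):
    """Row × grid double loop of single-row predictions."""
    cols = list(results.feature_names)
    j = cols.index(feature)
    M = X_df[cols].to_numpy(float)
    out = []
    for g in grid:
        preds = []
        for i in range(M.shape[0]):
            row = M[i].copy()
            row[j] = g
            preds.append(results.predict(row.reshape(1, -1))[0])
        out.append(np.mean(preds))
    return np.asarray(out)


def hand_kaplan_meier(times, death_flags):
    """Product-limit estimate computed from first principles.

    Returns (event_times, survival) at each distinct observed death time.
    """
    records = sorted(zip([float(t) for t in times], [bool(d) for d in death_flags]))
    distinct_death_times = sorted({t for t, d in records if d})
    surv = 1.0
    out_t, out_s = [], []
    for dt in distinct_death_times:
        at_risk = sum(1 for t, _ in records if t >= dt)
        deaths = sum(1 for t, d in records if d and t == dt)
        surv *= 1.0 - deaths / at_risk
        out_t.append(dt)
        out_s.append(surv)
    return out_t, out_s
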