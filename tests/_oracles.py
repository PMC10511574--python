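"""Brute-force oracles, independent of the package implementation.

Everything here is written from first principles (integer enumeration,
direct scans) so it can serve as the second route in dual-route checks.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_enum(a: int, b: int, c: int, d: int,
                alternative: str = "two_sided") -> Fraction:
    """Fisher's exact p by full enumeration with exact rational arithmetic.

    Enumerates every table with the observed margins; point probabilities
    are hypergeometric computed with integer binomials.
    """
    N = a + b + c + d
    K = a + b
    n1 = a + c
    if N == 0 or K in (0, N) or n1 in (0, N):
        return Fraction(1)
    denom = comb(N, n1)
    lo = max(0, K + n1 - N)
    hi = min(K, n1)
    probs = {x: Fraction(comb(K, x) * comb(N - K, n1 - x), denom)
             for x in range(lo, hi + 1)}
    obs = probs[a]
    if alternative == "two_sided":
        return sum((p for p in probs.values() if p <= obs), Fraction(0))
    if alternative == "greater":
        return sum((p for x, p in probs.items() if x >= a), Fraction(0))
    if alternative == "less":
        return sum((p for x, p in probs.items() if x <= a), Fraction(0))
    raise ValueError(alternative)


def count_table(reflux, symptom):
    """Counting oracle for the 2x2 window cross-tabulation."""
    a = b = c = d = 0
    for r, s in zip(reflux, symptom):
        if s and r:
            a += 1
        elif s and not r:
            b += 1
        elif not s and r:
            c += 1
        else:
            d += 1
    return a, b, c, d


def brute_force_reflux_labels(times, ph, dt, window_s, duration_s,
                              threshold=4.0, sustained_s=5.0,
                              drop_units=1.0, drop_span_s=5.0):
    """Direct per-window scan of the reflux-positivity rules.

    Criterion A: some maximal sub-threshold sample run covers at least
    ``sustained_s`` seconds inside the window.  Criterion B: two samples in
    the window at most ``drop_span_s`` apart with a drop > ``drop_units``.
    """
    import math
    n_win = math.ceil(duration_s / window_s)
    labels = [False] * n_win

    # maximal sub-threshold runs as covered intervals
    runs = []
    i = 0
    n = len(times)
    while i < n:
        if ph[i] < threshold:
            j = i
            while j + 1 < n and ph[j + 1] < threshold:
                j += 1
            runs.append((times[i], times[j] + dt))
            i = j + 1
        else:
            i += 1

    for w in range(n_win):
        ws = w * window_s
        we = min(ws + window_s, duration_s)
        for rs, re in runs:
            if min(re, we) - max(rs, ws) >= sustained_s:
                labels[w] = True
                break
        if labels[w]:
            continue
        idx = [k for k in range(n) if ws <= times[k] < we]
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                t1, t2 = times[idx[ii]], times[idx[jj]]
                if t2 - t1 > drop_span_s:
                    break
                if ph[idx[ii]] - ph[idx[jj]] > drop_units:
                    labels[w] = True
                    break
            if labels[w]:
                break
    return labels


def brute_force_sub4_time(ph, dt, threshold=4.0):
    """Total sub-threshold covered time by direct per-sample count."""
    return sum(dt for p in ph if p < threshold)


def mann_whitney_perm(x, y):
    """Exact two-sided Mann-Whitney p over all label permutations."""
    from itertools import combinations
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    nx = len(x)
    n = len(pooled)
    ranks = rankdata(pooled)
    mu = nx * (n - nx) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - nx * (nx + 1) / 2.0

    u_obs = u_of(range(nx))
    null = [u_of(idx) for idx in combinations(range(n), nx)]
    dev = abs(u_obs - mu)
    return float(np.mean([abs(u - mu) >= dev - 1e-12 for u in null]))
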