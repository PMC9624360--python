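"""Independent brute-force oracles used to verify the pipeline's numerics.

These deliberately avoid the code paths (and, where feasible, the library
routines) used by the implementation: the studentized-range tail is
computed by direct numerical integration of its defining double integral,
interval operations by per-base coverage counting, the hypergeometric tail
by exact binomial-coefficient enumeration, and Kaplan-Meier by the literal
product-limit recursion.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import integrate


def _phi(z: float) -> float:
    return math.exp(-z * z / 2) / math.sqrt(2 * math.pi)


def _Phi(z: float) -> float:
    return 0.5 * (1 + math.erf(z / math.sqrt(2)))


# ---------------------------------------------------- studentized range

def range_cdf(r: float, k: int) -> float:
    """P(range of k iid standard normals <= r), by numerical integration."""
    if r <= 0:
        return 0.0

    def integrand(z):
        return _phi(z) * (_Phi(z) - _Phi(z - r)) ** (k - 1)

    val, _ = integrate.quad(integrand, -12, 12, epsabs=1e-13, epsrel=1e-12, limit=400)
    return k * val


def studentized_range_sf(q: float, k: int, df: float) -> float:
    """P(Q > q) for the studentized range, integrating over the scale.

    s = sqrt(W/df) with W ~ chi2(df); f(s) ds weighting of the conditional
    range CDF at q*s. Independent of scipy.stats.studentized_range.
    """
    if q <= 0:
        return 1.0
    log_c = (df / 2) * math.log(df / 2) - math.lgamma(df / 2) + math.log(2)

    def integrand(s):
        log_f = log_c + (df - 1) * math.log(s) - df * s * s / 2
        return math.exp(log_f) * range_cdf(q * s, k)

    val, _ = integrate.quad(integrand, 0, np.inf, epsabs=1e-13, epsrel=1e-11, limit=400)
    return 1.0 - val


def hsd_q_direct(con: np.ndarray, ik1: np.ndarray) -> tuple[float, float, int, int]:
    """Two-group HSD statistic from first principles.

    Returns (difference, q, k, df) with MSW pooled over the two groups.
    """
    groups = [np.asarray(con, float), np.asarray(ik1, float)]
    k = 2
    n = sum(len(g) for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = n - k
    msw = ssw / df
    diff = groups[1].mean() - groups[0].mean()
    se = math.sqrt(msw / 2 * (1 / len(groups[0]) + 1 / len(groups[1])))
    return diff, abs(diff) / se, k, df


def permutation_p_two_group(con, ik1) -> float:
    """Exact permutation p-value of |q| over all group relabellings."""
    pooled = np.concatenate([np.asarray(con, float), np.asarray(ik1, float)])
    n1 = len(con)
    _, q_obs, _, _ = hsd_q_direct(con, ik1)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        _, q, _, _ = hsd_q_direct(pooled[mask], pooled[~mask])
        count += q >= q_obs - 1e-12
        total += 1
    return count / total


# ----------------------------------------------------------- BH step-up

def bh_stepup(p: list[float]) -> list[float]:
    """Literal Benjamini-Hochberg: adjusted_i = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


# ----------------------------------------------------------- intervals

def coverage_vector(peaks, length: int) -> np.ndarray:
    """Per-base boolean coverage of [(start, end), ...] on [0, length)."""
    cov = np.zeros(length, bool)
    for s, e in peaks:
        cov[max(s, 0) : min(e, length)] = True
    return cov


def brute_reproducible(peak_sets: list[list[tuple[int, int]]], length: int):
    """Positions covered in every set, returned as merged intervals."""
    cov = np.ones(length, bool)
    for peaks in peak_sets:
        cov &= coverage_vector(peaks, length)
    out = []
    start = None
    for i, c in enumerate(cov):
        if c and start is None:
            start = i
        elif not c and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, length))
    return out


def brute_window_links(anchors, tss_list, window: int):
    """All (peak_index, gene_index) with |anchor - tss| <= window (closed)."""
    return {
        (pi, gi)
        for pi, a in enumerate(anchors)
        for gi, t in enumerate(tss_list)
        if abs(a - t) <= window
    }


# ------------------------------------------------------- hypergeometric

def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k), X ~ Hypergeom(N, K, n), by exact enumeration."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(max(k, 0, K + n - N), min(K, n) + 1)
    )
    return total / denom


# -------------------------------------------------------------- survival

def km_product_limit(times, events):
    """Hand product-limit: {event time: S(t)} over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


def logrank_two_group_chi2(times, events, group) -> float:
    """Textbook two-group log-rank chi-square (observed vs expected)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0
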