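"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (loops, enumeration, exhaustive
search) and shares no code with the package paths it checks.
"""

import itertools
import math

import numpy as np


def tom_reference(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap of an adjacency with unit diagonal."""
    n = a.shape[0]
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l = 0.0
            for u in range(n):
                if u != i and u != j:
                    l += a[i, u] * a[u, j]
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l + a[i, j]) / (min(k_i, k_j) + 1.0 - a[i, j])
    return tom


def upgma_reference(d: np.ndarray):
    """Naive UPGMA agglomeration on a dissimilarity matrix.

    Returns the sorted list of merge heights (the tree shape is checked
    elsewhere; heights identify the trace for a fixed input).
    """
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = np.mean([d[i, j] for i in clusters[a]
                            for j in clusters[b]])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def cox_grid_search(x, t, e, lo=-5.0, hi=5.0, tol=1e-6):
    """Maximise the Efron partial likelihood by golden-section search."""

    def loglik(beta):
        x_ = np.asarray(x, float)
        t_ = np.asarray(t, float)
        e_ = np.asarray(e, int)
        ll = 0.0
        for time in np.unique(t_[e_ == 1]):
            dead = (t_ == time) & (e_ == 1)
            risk = t_ >= time
            d = int(dead.sum())
            ll += beta * x_[dead].sum()
            s0_risk = np.exp(beta * x_[risk]).sum()
            s0_dead = np.exp(beta * x_[dead]).sum()
            for j in range(d):
                ll -= math.log(s0_risk - (j / d) * s0_dead)
        return ll

    phi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, dd = b - phi * (b - a), a + phi * (b - a)
    fc, fd = loglik(c), loglik(dd)
    while b - a > tol:
        if fc > fd:
            b, dd, fd = dd, c, fc
            c = b - phi * (b - a)
            fc = loglik(c)
        else:
            a, c, fc = c, dd, fd
            dd = a + phi * (b - a)
            fd = loglik(dd)
    return (a + b) / 2


def bh_reference(p):
    """Hand step-up Benjamini-Hochberg adjustment."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        adj[i] = val
        prev = val
    return adj


def hypergeom_tail_enumeration(n_universe, set_size, query_size, k_min):
    """P(overlap >= k_min) by exact combinatorial summation."""
    total = math.comb(n_universe, query_size)
    acc = 0
    for k in range(k_min, min(set_size, query_size) + 1):
        acc += (math.comb(set_size, k)
                * math.comb(n_universe - set_size, query_size - k))
    return acc / total


def km_reference(times, events):
    """Hand product-limit estimator: returns (event_times, S) including
    the S(0)=1 starting point."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    uniq = np.unique(times)
    s = 1.0
    out_t, out_s = [0.0], [1.0]
    for time in uniq:
        at_risk = (times >= time).sum()
        d = ((times == time) & (events == 1)).sum()
        if d > 0:
            s *= 1.0 - d / at_risk
        out_t.append(float(time))
        out_s.append(float(s))
    return np.array(out_t), np.array(out_s)


def connectivity_reference(a: np.ndarray, labels=None):
    """Nested-loop k.total / k.in."""
    n = a.shape[0]
    k_total = np.zeros(n)
    k_in = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            k_total[i] += a[i, j]
            if labels is not None and labels[i] == labels[j] \
                    and labels[i] != "grey":
                k_in[i] += a[i, j]
    return k_total, k_in


def pearson_two_pass(x: np.ndarray) -> np.ndarray:
    """Two-pass pairwise Pearson correlation matrix."""
    n = x.shape[0]
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi = x[i] - x[i].mean()
            xj = x[j] - x[j].mean()
            r[i, j] = r[j, i] = (
                (xi * xj).sum()
                / math.sqrt((xi ** 2).sum() * (xj ** 2).sum()))
    return r
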