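"""Independent brute-force oracles used to validate the implementation.

Everything here is written as literally as possible (explicit loops,
explicit CDF tables, exhaustive enumeration) and stays independent of the
code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def mv_statistic_oracle(x, y) -> float:
    """MV index by explicit empirical-CDF tabulation over all (theta, j) pairs."""
    x = list(map(float, x))
    y = list(y)
    n = len(x)
    classes = sorted(set(y))
    total = 0.0
    for theta in classes:
        n_theta = sum(1 for v in y if v == theta)
        p_theta = n_theta / n
        for j in range(n):
            f_cond = sum(1 for v in range(n) if x[v] <= x[j] and y[v] == theta) / n_theta
            f_marg = sum(1 for v in range(n) if x[v] <= x[j]) / n
            total += p_theta * (f_cond - f_marg) ** 2
    return total


def gcc_oracle(values, rho: float = 0.5) -> np.ndarray:
    """Corrected GCC matrix by a literal triple loop with global extremes."""
    x = np.asarray(values, dtype=float)
    m, n = x.shape
    raw = np.empty((m, m))
    for p in range(m):
        dmin = min(abs(x[t_gene, t] - x[p, t]) for t_gene in range(m) for t in range(n))
        dmax = max(abs(x[t_gene, t] - x[p, t]) for t_gene in range(m) for t in range(n))
        for q in range(m):
            acc = 0.0
            for k in range(n):
                delta_k = abs(x[p, k] - x[q, k])
                acc += (dmin + rho * dmax) / (delta_k + rho * dmax)
            raw[p, q] = acc / n
    sym = (raw + raw.T) / 2.0
    for p in range(m):
        sym[p, p] = 1.0
    return sym


def ising_conditional_oracle(
    edges, m, p, omega_rest, xi=None, h=0.0, tau1=0.01, tau2=0.01, delta=0.95,
    log_f0=None, log_f1=None,
):
    """P(w_p = +1 | evidence, w_-p) from the fully enumerated joint.

    ``edges`` is a list of (u, v, weight); ``omega_rest`` fixes every label
    except node ``p``.  When ``log_f0``/``log_f1`` are given (length-m
    arrays of per-gene evidence log densities) the joint includes the
    evidence term; otherwise the conditional is that of the bare Ising
    prior.  The partition function Z is summed explicitly over all 2^m
    configurations.
    """

    def log_weight(omega):
        e = -h * sum(1 for w in omega if w == +1)
        for u, v, wt in edges:
            if omega[u] == +1 and omega[v] == +1:
                e += tau1 * wt
            if omega[u] == -1 and omega[v] == -1 and wt > delta:
                e -= tau2 * wt
        if log_f0 is not None:
            for i, w in enumerate(omega):
                e += log_f1[i] if w == +1 else log_f0[i]
        return e

    z = 0.0
    joint = {}
    for labels in itertools.product([-1, +1], repeat=m):
        w = math.exp(log_weight(labels))
        joint[labels] = w
        z += w
    plus = list(omega_rest)
    plus[p] = +1
    minus = list(omega_rest)
    minus[p] = -1
    p_plus = joint[tuple(plus)] / z
    p_minus = joint[tuple(minus)] / z
    return p_plus / (p_plus + p_minus)


def graph_stats_oracle(nodes, edges):
    """Density, average degree, mean BFS path length over connected pairs,
    and mean local clustering (degree < 2 counts 0) — all from scratch."""
    nodes = list(nodes)
    n = len(nodes)
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    e = len(edges)
    density = 2 * e / (n * (n - 1)) if n >= 2 else 0.0
    avg_degree = 2 * e / n if n else 0.0

    total, pairs = 0, 0
    for src in nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for tgt, d in dist.items():
            if tgt != src:
                total += d
                pairs += 1
    avg_path = total / pairs if pairs else 0.0

    clustering = []
    for u in nodes:
        k = len(adj[u])
        if k < 2:
            clustering.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(adj[u], 2) if b in adj[a]
        )
        clustering.append(2 * links / (k * (k - 1)))
    avg_clust = sum(clustering) / n if n else 0.0
    return density, avg_degree, avg_path, avg_clust


def quantile_oracle(values, q: float) -> float:
    """Linear-interpolation (type 7) quantile from sorted order statistics."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac
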