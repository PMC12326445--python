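"""Independent straight-line oracles for the test suite.

Everything here is written as plain Python loops from the defining
formulas, deliberately sharing no code with the package's vectorised
implementations.
"""

from __future__ import annotations

import math


def strengths(W) -> list[float]:
    n = len(W)
    return [sum(W[i][j] for j in range(n)) for i in range(n)]


def relative_strengths(W, corrected: bool) -> list[float]:
    n = len(W)
    s = strengths(W)
    out = []
    for i in range(n):
        neigh = [j for j in range(n) if W[i][j] > 0]
        if not corrected:
            out.append(s[i] / (sum(s[j] for j in neigh) / len(neigh)))
        else:
            terms = [(s[j] - W[i][j]) / (s[i] - W[i][j])
                     for j in neigh if s[i] - W[i][j] > 0]
            out.append(1.0 / (sum(terms) / len(terms)))
    return out


def sample_sd(xs) -> float:
    n = len(xs)
    mu = sum(xs) / n
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / (n - 1))


def rsv(W, corrected: bool) -> float:
    return sample_sd(relative_strengths(W, corrected))


def hrsv(W, w: int, corrected: bool, basis=None) -> float:
    n = len(W)
    if basis is None:
        basis = strengths(W)
    r = relative_strengths(W, corrected)
    order = sorted(range(n), key=lambda i: (basis[i], i))
    rs = [r[i] for i in order]
    sds = [sample_sd(rs[k:k + w]) for k in range(n - w + 1)]
    return sum(sds) / len(sds)


def floyd_warshall_efficiency(W) -> float:
    n = len(W)
    inf = float("inf")
    d = [[0.0 if i == j else (1.0 / W[i][j] if W[i][j] > 0 else inf)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return sum(1.0 / d[i][j] for i in range(n) for j in range(n)
               if i != j and d[i][j] < inf) / (n * (n - 1))


def endpoint_pearson_assortativity(W) -> float:
    """Pearson correlation of strengths over directed edge endpoints."""
    n = len(W)
    s = strengths(W)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if W[i][j] > 0:
                xs.append(s[i])
                ys.append(s[j])
    m = len(xs)
    mx = sum(xs) / m
    my = sum(ys) / m
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / m
    vx = sum((x - mx) ** 2 for x in xs) / m
    vy = sum((y - my) ** 2 for y in ys) / m
    return cov / math.sqrt(vx * vy)


def onnela_mean_clustering(W) -> float:
    n = len(W)
    wmax = max(W[i][j] for i in range(n) for j in range(n))
    c_sum = 0.0
    for i in range(n):
        neigh = [j for j in range(n) if W[i][j] > 0]
        k = len(neigh)
        if k < 2:
            continue
        tri = 0.0
        for j in neigh:
            for l in neigh:
                if j != l and W[j][l] > 0:
                    tri += ((W[i][j] / wmax) * (W[j][l] / wmax) * (W[l][i] / wmax)) ** (1.0 / 3.0)
        c_sum += tri / (k * (k - 1))
    return c_sum / n


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(1.0, p[i] * m / rank_from_end)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj
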