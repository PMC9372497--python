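"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written from first principles (explicit
sums, definition-level loops) and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pearson_sum_formula(x, y) -> float:
    """Textbook product-moment correlation via the Sigma formula."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def bh_stepup(pvals, q) -> list[bool]:
    """Benjamini-Hochberg by its step-up definition: reject p(1..k*) where
    k* is the largest k with p(k) <= k*q/m."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    kstar = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * q / m:
            kstar = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= kstar:
            reject[i] = True
    return reject


def t_unpaired(x, y) -> float:
    """Two-sided pooled-variance two-sample t-test p-value by formula."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((a - mx) ** 2 for a in x) / (nx - 1)
    vy = sum((b - my) ** 2 for b in y) / (ny - 1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2 * stats.t.sf(abs(t), nx + ny - 2)


def t_paired(x, y) -> float:
    """Two-sided paired t-test p-value by formula."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    md = sum(d) / n
    vd = sum((v - md) ** 2 for v in d) / (n - 1)
    t = md / math.sqrt(vd / n)
    return 2 * stats.t.sf(abs(t), n - 1)


# ---------------------------------------------------------------------------
# graph metrics on a boolean adjacency matrix (induced-subgraph scope)


def induced(adj: np.ndarray, idx) -> np.ndarray:
    idx = list(idx)
    return np.array([[bool(adj[i, j]) for j in idx] for i in idx])


def mean_degree_centrality(adj: np.ndarray, idx) -> float:
    sub = induced(adj, idx)
    k = len(sub)
    degs = [sum(1 for j in range(k) if sub[i][j]) for i in range(k)]
    return sum(d / (k - 1) for d in degs) / k


def nodal_degree_centrality(adj: np.ndarray, i: int) -> float:
    n = adj.shape[0]
    return sum(1 for j in range(n) if adj[i, j]) / (n - 1)


def average_clustering(adj: np.ndarray, idx) -> float:
    sub = induced(adj, idx)
    k = len(sub)
    coeffs = []
    for i in range(k):
        nbrs = [j for j in range(k) if sub[i][j]]
        d = len(nbrs)
        if d < 2:
            coeffs.append(0.0)
            continue
        links = sum(
            1
            for a in range(d)
            for b in range(a + 1, d)
            if sub[nbrs[a]][nbrs[b]]
        )
        coeffs.append(2 * links / (d * (d - 1)))
    return sum(coeffs) / k


def shortest_paths(sub: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by Floyd-Warshall (inf = unreachable)."""
    k = len(sub)
    dist = np.full((k, k), np.inf)
    for i in range(k):
        dist[i, i] = 0.0
        for j in range(k):
            if i != j and sub[i][j]:
                dist[i, j] = 1.0
    for m in range(k):
        for i in range(k):
            for j in range(k):
                if dist[i, m] + dist[m, j] < dist[i, j]:
                    dist[i, j] = dist[i, m] + dist[m, j]
    return dist


def global_efficiency(adj: np.ndarray, idx) -> float:
    sub = induced(adj, idx)
    k = len(sub)
    if k < 2:
        return 0.0
    dist = shortest_paths(sub)
    total = 0.0
    for i in range(k):
        for j in range(k):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (k * (k - 1))


# ---------------------------------------------------------------------------
# independent end-to-end prefix evaluation (Algorithm-2 oracle)


def prefix_pvalues(stack, main_ids, supp_ids, q=0.05, mode="positive",
                   paired=True) -> list[float]:
    """Re-evaluate every candidate prefix from the raw stack arrays using
    only oracle components (BH step-up, loop-based degree means, scipy
    t-test)."""
    qids = [r.qualified_id for r in stack.rois]
    pos = {qid: i for i, qid in enumerate(qids)}
    C, S, N, _ = stack.matrices.shape
    # threshold every slice with the oracle BH
    adjs = {}
    for c in range(C):
        for s in range(S):
            pmat = stack.pvals[c, s]
            iu = [(i, j) for i in range(N) for j in range(i + 1, N)]
            rej = bh_stepup([pmat[i, j] for i, j in iu], q)
            adj = np.zeros((N, N), dtype=bool)
            for keep, (i, j) in zip(rej, iu):
                ok = keep and (
                    mode == "absolute" or stack.matrices[c, s][i, j] > 0
                )
                adj[i, j] = adj[j, i] = ok
            adjs[(c, s)] = adj
    out = []
    for plen in range(len(supp_ids) + 1):
        members = [pos[q_] for q_ in list(main_ids) + list(supp_ids)[:plen]]
        values = np.array(
            [
                [mean_degree_centrality(adjs[(c, s)], members)
                 for s in range(S)]
                for c in range(C)
            ]
        )
        if paired:
            diff = values[0] - values[1]
            if np.ptp(diff) == 0:
                out.append(1.0 if diff[0] == 0 else 0.0)
            else:
                out.append(float(stats.ttest_rel(values[0],
                                                 values[1]).pvalue))
        else:
            out.append(float(stats.ttest_ind(values[0], values[1]).pvalue))
    return out
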