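"""Independent brute-force oracles used by the tests.

Everything here is implemented with plain Python loops, straight from the
defining equations, deliberately sharing no code with the package.
"""

import itertools
import math

import numpy as np


def brute_memberships(X, y, k_init):
    """Constrained training memberships by literal enumeration."""
    X = [list(map(float, row)) for row in X]
    n = len(X)
    classes = sorted(set(int(v) for v in y))
    U = []
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            d = math.dist(X[i], X[j])
            dists.append((d, j))
        dists.sort(key=lambda t: (t[0], t[1]))
        neigh = [j for _, j in dists[:k_init]]
        row = []
        for c in classes:
            nj = sum(1 for j in neigh if int(y[j]) == c)
            val = nj / k_init * 0.49
            if c == int(y[i]):
                val += 0.51
            row.append(val)
        U.append(row)
    return np.array(U)


def brute_predict_memberships(X, y, query, k, m, k_init=None):
    """Fuzzy-weighted membership vector for one query, by enumeration."""
    if k_init is None:
        k_init = k
    U = brute_memberships(X, y, k_init)
    classes = sorted(set(int(v) for v in y))
    dists = sorted(
        ((math.dist(list(map(float, query)), list(map(float, X[j]))), j)
         for j in range(len(X))),
        key=lambda t: (t[0], t[1]),
    )[:k]
    zero = [j for d, j in dists if d < 1e-12]
    if zero:
        return np.mean([U[j] for j in zero], axis=0)
    num = np.zeros(len(classes))
    den = 0.0
    for d, j in dists:
        w = (1.0 / d) ** (2.0 / (m - 1.0))
        num += w * U[j]
        den += w
    return num / den


def brute_classify(X, y, query, k, m):
    u = brute_predict_memberships(X, y, query, k, m)
    classes = sorted(set(int(v) for v in y))
    best = max(range(len(classes)), key=lambda c: (u[c], -c))
    return classes[best]


def permutation_ranksum_pvalue(a, b):
    """Exact two-sided rank-sum p-value by enumerating all assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)
    ranks = {}
    for v in set(pooled):
        pos = [i for i, x in enumerate(sorted(pooled)) if x == v]
        ranks[v] = sum(p + 1 for p in pos) / len(pos)  # midrank
    observed = sum(ranks[v] for v in a)
    stats = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        stats.append(sum(ranks[pooled[i]] for i in combo))
    mean = sum(stats) / len(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(observed - mean) - 1e-12)
    return extreme / len(stats)


def paired_cluster_dataset(offset=0.35, seed=0, grid=4, spacing=1.5):
    """Checkerboard of same-class point pairs.

    Partner distance ``2 * offset``; the four adjacent clusters (opposite
    class) sit ``spacing`` away, so nearest-neighbor prediction is right
    whenever the partner is in the training split while wider
    neighborhoods recruit opposite-class points.  Inner-CV error is
    strictly minimized at k = 1 once the fuzzy strength is kept at or
    above 1.5.
    """
    rng = np.random.default_rng(seed)
    pts, ys = [], []
    for i in range(grid):
        for j in range(grid):
            c = np.array([i * spacing, j * spacing])
            d = rng.normal(size=2)
            d /= np.linalg.norm(d)
            pts += [c + offset * d, c - offset * d]
            ys += [(i + j) % 2] * 2
    return np.array(pts), np.array(ys)
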