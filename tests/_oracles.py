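"""Independent brute-force oracles used to validate the package implementations.

Everything here is written as plain loops over definitions, deliberately
without reusing any code path from the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# goodness-of-clustering index oracles (labels are any hashable cluster ids)
# ---------------------------------------------------------------------------

def clusters_of(labels):
    out = {}
    for i, c in enumerate(labels):
        out.setdefault(c, []).append(i)
    return out


def oracle_indval(x, labels):
    x = np.asarray(x, dtype=float)
    cl = clusters_of(labels)
    scores = []
    for j in range(x.shape[1]):
        means = {c: np.mean([x[i, j] for i in idx]) for c, idx in cl.items()}
        tot = sum(means.values())
        best = 0.0
        for c, idx in cl.items():
            a = means[c] / tot if tot > 0 else 0.0
            b = np.mean([1.0 if x[i, j] > 0 else 0.0 for i in idx])
            best = max(best, 100.0 * a * b)
        scores.append(best)
    return float(np.mean(scores))


def oracle_isamic(x, labels):
    x = np.asarray(x, dtype=float) > 0
    cl = clusters_of(labels)
    scores = []
    for j in range(x.shape[1]):
        devs = [abs(np.mean([x[i, j] for i in idx]) - 0.5) for idx in cl.values()]
        scores.append(2.0 * np.mean(devs))
    return float(np.mean(scores))


def _hypergeom_tail(k, big_n, big_k, n_draw):
    """P(X >= k) for X ~ Hypergeometric(big_n, big_k, n_draw), by summation."""
    total = 0.0
    for x in range(k, min(big_k, n_draw) + 1):
        total += (math.comb(big_k, x) * math.comb(big_n - big_k, n_draw - x)
                  / math.comb(big_n, n_draw))
    return total


def oracle_optimclass(x, labels, alpha=0.001):
    x = np.asarray(x, dtype=float) > 0
    n = x.shape[0]
    cl = clusters_of(labels)
    count = 0
    for j in range(x.shape[1]):
        big_k = int(x[:, j].sum())
        if big_k == 0 or big_k == n:
            continue
        for idx in cl.values():
            in_c = int(sum(x[i, j] for i in idx))
            p = _hypergeom_tail(in_c, n, big_k, len(idx))
            if p < alpha:
                count += 1
    return float(count)


def oracle_tabdev(x, labels):
    x = np.asarray(x, dtype=float) > 0
    cl = clusters_of(labels)
    dev = 0.0
    for j in range(x.shape[1]):
        for idx in cl.values():
            nk = len(idx)
            njk = sum(1 for i in idx if x[i, j])
            p = njk / nk
            t = 0.0
            if njk > 0:
                t += njk * math.log(p)
            if nk - njk > 0:
                t += (nk - njk) * math.log(1 - p)
            dev += -2.0 * t
    return float(dev)


def oracle_totchi(x, labels):
    x = np.asarray(x, dtype=float)
    total_inertia = 0.0
    for idx in clusters_of(labels).values():
        sub = x[idx]
        sub = sub[:, sub.sum(axis=0) > 0]
        sub = sub[sub.sum(axis=1) > 0]
        if sub.shape[0] < 2 or sub.shape[1] < 2:
            continue
        grand = sub.sum()
        chi2 = 0.0
        for r in range(sub.shape[0]):
            for c in range(sub.shape[1]):
                e = sub[r].sum() * sub[:, c].sum() / grand
                chi2 += (sub[r, c] - e) ** 2 / e
        total_inertia += chi2 / grand
    return float(total_inertia)


def oracle_disdiam(d, labels):
    diams = []
    for idx in clusters_of(labels).values():
        if len(idx) < 2:
            diams.append(0.0)
        else:
            diams.append(max(d[i, j] for i in idx for j in idx))
    return float(np.mean(diams))


def oracle_partana(d, labels):
    within, between = [], []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(d[i, j])
    if not within or not between:
        return None
    wm = np.mean(within)
    return math.inf if wm == 0 else float(np.mean(between) / wm)


def oracle_silhouette(d, labels):
    cl = clusters_of(labels)
    n = len(labels)
    s = []
    for i in range(n):
        own = cl[labels[i]]
        if len(own) == 1:
            s.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own if j != i])
        b = min(np.mean([d[i, j] for j in idx])
                for c, idx in cl.items() if c != labels[i])
        denom = max(a, b)
        s.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(s))


def oracle_wss(d, labels):
    total = 0.0
    for idx in clusters_of(labels).values():
        ss = sum(d[i, j] ** 2 for i in idx for j in idx)
        total += ss / (2.0 * len(idx))
    return float(total)


def oracle_ch(d, labels):
    n = len(labels)
    k = len(set(labels))
    if k <= 1 or k >= n:
        return None
    tss = sum(d[i, j] ** 2 for i in range(n) for j in range(n)) / (2.0 * n)
    wss = oracle_wss(d, labels)
    bss = tss - wss
    return math.inf if wss == 0 else (bss / (k - 1)) / (wss / (n - k))


def oracle_wss_coords(x, labels):
    """Coordinate-based WSS: sum of squared distances to cluster centroids."""
    x = np.asarray(x, dtype=float)
    total = 0.0
    for idx in clusters_of(labels).values():
        mu = x[idx].mean(axis=0)
        total += float(((x[idx] - mu) ** 2).sum())
    return total


def oracle_ch_coords(x, labels):
    """Classical coordinate-based Calinski-Harabasz."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape[0], len(set(labels))
    mu = x.mean(axis=0)
    wss = oracle_wss_coords(x, labels)
    bss = 0.0
    for idx in clusters_of(labels).values():
        m = x[idx].mean(axis=0)
        bss += len(idx) * float(((m - mu) ** 2).sum())
    return (bss / (k - 1)) / (wss / (n - k))


# ---------------------------------------------------------------------------
# PAM and label-matching oracles
# ---------------------------------------------------------------------------

def exhaustive_pam_cost(d, k):
    """Global optimum of the k-medoid objective by enumerating all medoid sets."""
    n = d.shape[0]
    best = math.inf
    for medoids in itertools.combinations(range(n), k):
        cost = sum(min(d[i, m] for m in medoids) for i in range(n))
        best = min(best, cost)
    return best


def exhaustive_match_agreement(confusion):
    """Best total agreement over all injective column->row assignments."""
    c = np.asarray(confusion, dtype=float)
    rows, cols = c.shape
    best = 0.0
    if cols <= rows:
        for perm in itertools.permutations(range(rows), cols):
            best = max(best, sum(c[perm[j], j] for j in range(cols)))
    else:
        for perm in itertools.permutations(range(cols), rows):
            best = max(best, sum(c[i, perm[i]] for i in range(rows)))
    return best
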