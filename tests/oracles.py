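"""Independent brute-force reference implementations used only by tests.

Everything here is written as literally as possible (plain loops, no
shared code with the package) so it can serve as a second route when
checking the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_p_distance(a, b) -> float:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


def brute_jaccard(a, b) -> float:
    shared = sum(1 for x, y in zip(a, b) if x == 1 and y == 1)
    union = sum(1 for x, y in zip(a, b) if x == 1 or y == 1)
    if union == 0:
        return 0.0
    return 1.0 - shared / union


def brute_gower(rows: np.ndarray, missing: int = -1) -> np.ndarray:
    """Pairwise Gower distances by explicit loops; ranges from observed data."""
    n, L = rows.shape
    ranges = []
    for l in range(L):
        obs = [rows[i, l] for i in range(n) if rows[i, l] != missing]
        ranges.append(max(obs) - min(obs) if obs else 0)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num, cnt = 0.0, 0
            for l in range(L):
                if rows[i, l] == missing or rows[j, l] == missing:
                    continue
                if ranges[l] == 0:
                    continue
                num += abs(rows[i, l] - rows[j, l]) / ranges[l]
                cnt += 1
            d[i, j] = num / cnt if cnt else 0.0
    return d


def _rank_with_ties(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_anosim_r(dvals: np.ndarray, labels: list) -> float:
    """Literal rank formula: R = (mean between rank - mean within rank) / (n(n-1)/4)."""
    n = len(labels)
    pair_d, pair_within = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pair_d.append(dvals[i, j])
            pair_within.append(labels[i] == labels[j])
    ranks = _rank_with_ties(pair_d)
    within = [r for r, w in zip(ranks, pair_within) if w]
    between = [r for r, w in zip(ranks, pair_within) if not w]
    return (sum(between) / len(between) - sum(within) / len(within)) / (n * (n - 1) / 4)


def exhaustive_anosim_p(dvals: np.ndarray, labels: list) -> float:
    """P(R_perm >= R_obs) over all n! label orderings."""
    obs = brute_anosim_r(dvals, labels)
    count = total = 0
    for perm in itertools.permutations(labels):
        total += 1
        if brute_anosim_r(dvals, list(perm)) >= obs - 1e-12:
            count += 1
    return count / total


def brute_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def brute_mantel_r(d1: np.ndarray, d2: np.ndarray) -> float:
    n = d1.shape[0]
    v1 = [d1[i, j] for i in range(n) for j in range(i + 1, n)]
    v2 = [d2[i, j] for i in range(n) for j in range(i + 1, n)]
    return brute_pearson(v1, v2)


def exhaustive_mantel_p(d1: np.ndarray, d2: np.ndarray) -> float:
    """One-sided P(r_perm >= r_obs) over all n! joint row/col permutations of d2."""
    n = d1.shape[0]
    obs = brute_mantel_r(d1, d2)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        dp = d2[np.ix_(perm, perm)]
        if brute_mantel_r(d1, dp) >= obs - 1e-12:
            count += 1
    return count / total


def brute_greedy_filter(rows: dict, locus_order: list, pairs: list) -> list:
    """Literal remove-recompute-compare pass; returns removed locus ids.

    ``rows`` maps sample id -> dict locus id -> 0/1.
    """
    loci = list(locus_order)

    def dist_sum(current_loci):
        total = 0.0
        for a, b in pairs:
            mism = sum(1 for l in current_loci if rows[a][l] != rows[b][l])
            total += mism / len(current_loci)
        return total

    removed = []
    current = dist_sum(loci)
    for locus in list(locus_order):
        if locus not in loci or len(loci) == 1:
            continue
        trial = [l for l in loci if l != locus]
        s = dist_sum(trial)
        if s < current:
            loci = trial
            current = s
            removed.append(locus)
    return removed


def naive_nmds_stress(dvals: np.ndarray, k: int, starts: list[np.ndarray],
                      n_iter: int = 2000, lr: float = 0.05) -> float:
    """Gradient-descent NMDS (isotonic regression via PAVA), best of given starts."""

    def pava(y, order):
        # pool-adjacent-violators isotonic fit of y taken in the given order
        yhat = [y[i] for i in order]
        out = []
        for v in yhat:
            out.append([v, 1.0])
            while len(out) > 1 and out[-2][0] > out[-1][0]:
                v2, w2 = out.pop()
                v1, w1 = out.pop()
                out.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
        fit_sorted = []
        for v, w in out:
            fit_sorted.extend([v] * int(round(w)))
        fit = [0.0] * len(y)
        for pos, idx in enumerate(order):
            fit[idx] = fit_sorted[pos]
        return np.array(fit)

    n = dvals.shape[0]
    iu, ju = np.triu_indices(n, 1)
    delta = dvals[iu, ju]
    order = list(np.argsort(delta, kind="stable"))
    best = np.inf
    for x0 in starts:
        x = x0.copy()
        for _ in range(n_iter):
            diff = x[iu] - x[ju]
            dist = np.sqrt((diff**2).sum(axis=1))
            dist = np.maximum(dist, 1e-12)
            dhat = pava(dist, order)
            ss = (dist**2).sum()
            stress = np.sqrt(((dhat - dist) ** 2).sum() / ss)
            if stress < 1e-9:
                break
            # gradient of stress-1 wrt configuration (dhat treated constant)
            s2 = ((dhat - dist) ** 2).sum()
            coef = ((dhat - dist) * (-1.0) / ss - s2 * (-dist) / ss**2) / (
                2 * max(stress, 1e-12)
            )
            grad = np.zeros_like(x)
            g_pair = (coef * 2)[:, None] * diff / dist[:, None]
            np.add.at(grad, iu, g_pair)
            np.add.at(grad, ju, -g_pair)
            x = x - lr * grad
        diff = x[iu] - x[ju]
        dist = np.maximum(np.sqrt((diff**2).sum(axis=1)), 1e-12)
        dhat = pava(dist, order)
        stress = np.sqrt(((dhat - dist) ** 2).sum() / (dist**2).sum())
        best = min(best, stress)
    return float(best)
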