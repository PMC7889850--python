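"""Permutation statistics and ordination built from first principles.

Implements rank-based analysis of similarity (Global R with a label
permutation test), the Mantel matrix-correlation test (Pearson, joint
row/column permutation) and non-metric multidimensional scaling (Kruskal
stress-1, isotonic regression + Guttman majorization, multiple restarts).

p-values follow the add-one convention: the observed statistic counts as
one permutation, so p = (#{permuted >= observed} + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .io_formats import DistanceMatrix


@dataclass
class AnosimResult:
    global_R: float
    p_value: float
    n_permutations: int
    permuted_R: np.ndarray | None = None

    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


@dataclass
class Ordination:
    coordinates: np.ndarray  # (n, k)
    stress: float  # Kruskal stress-1 of the best restart
    converged: bool
    stress_history: list[float] = field(default_factory=list)


def significance_stars(p: float, levels: tuple[float, ...] = (0.05, 0.01)) -> str:
    """Star string for a p-value: '*' at 0.05, '**' at 0.01."""
    return "*" * sum(p <= lvl for lvl in levels)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def _group_codes(labels: Sequence[str], groups: Mapping[str, str]) -> np.ndarray:
    missing = [l for l in labels if l not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    cats = {g: i for i, g in enumerate(dict.fromkeys(groups[l] for l in labels))}
    return np.array([cats[groups[l]] for l in labels])


def anosim(
    d: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 9999,
    seed: int = 0,
    keep_permuted: bool = False,
) -> AnosimResult:
    """Analysis of similarity on a labelled distance matrix.

    All n(n-1)/2 pairwise distances are ranked (average ranks for ties);
    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).
    The null distribution comes from shuffling group labels.
    """
    codes = _group_codes(d.labels, groups)
    counts = np.bincount(codes)
    if counts.size < 2:
        raise ValueError("anosim needs >= 2 groups")
    if (counts < 2).any():
        small = [g for g, c in zip(dict.fromkeys(groups[l] for l in d.labels), counts)
                 if c < 2]
        raise ValueError(f"groups of size 1 have no within-group pairs: {small}")
    n = d.n
    iu, ju = np.triu_indices(n, 1)
    ranks = rankdata(d.values[iu, ju])
    denom = n * (n - 1) / 4.0

    def r_stat(c: np.ndarray) -> float:
        within = c[iu] == c[ju]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    observed = r_stat(codes)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        permuted[k] = r_stat(rng.permutation(codes))
    p = (np.count_nonzero(permuted >= observed) + 1) / (n_perm + 1)
    return AnosimResult(
        global_R=observed,
        p_value=float(p),
        n_permutations=n_perm,
        permuted_R=permuted if keep_permuted else None,
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: Pearson correlation of upper triangles, one-sided
    (r >= observed), null by jointly permuting rows+columns of d2.

    d2 is aligned to d1's label order before anything is computed.
    """
    d2 = d2.reorder(d1.labels)
    n = d1.n
    iu, ju = np.triu_indices(n, 1)
    v1 = d1.values[iu, ju]
    m2 = d2.values
    v2 = m2[iu, ju]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("mantel r undefined: zero variance in a distance triangle")
    z1 = (v1 - v1.mean()) / v1.std()

    def corr(v: np.ndarray) -> float:
        return float(np.dot(z1, (v - v.mean()) / v.std()) / v.size)

    observed = corr(v2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        vp = m2[np.ix_(p_idx, p_idx)][iu, ju]
        if corr(vp) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=observed, p_value=float(p), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def _kruskal_stress(dhat: np.ndarray, dist: np.ndarray) -> float:
    ss = float(np.sum(dist**2))
    if ss == 0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - dist) ** 2) / ss))


def _classical_mds(dvals: np.ndarray, k: int) -> np.ndarray:
    n = dvals.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dvals**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(lam)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    restarts: int = 50,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    The first start is the classical (metric) MDS configuration, the
    remaining ``restarts - 1`` are random.  Each start alternates isotonic
    regression of configuration distances on the input dissimilarities
    with a Guttman transform until the stress improvement drops below
    ``tol``.  The best restart's configuration is returned.
    """
    n = d.n
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")
    if not np.isfinite(d.values).all():
        raise ValueError("non-finite distances")
    delta = d.condensed()
    if np.all(delta == 0):
        return Ordination(np.zeros((n, k)), 0.0, True, [0.0])
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression()
    best: Ordination | None = None
    scale = delta.max()
    for start in range(max(1, restarts)):
        if start == 0:
            x = _classical_mds(d.values, k)
        else:
            x = rng.normal(scale=scale, size=(n, k))
        history: list[float] = []
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            dist = pdist(x)
            dhat = iso.fit(delta, dist).predict(delta)
            stress = _kruskal_stress(dhat, dist)
            history.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform with disparities dhat
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / dist, 0.0)
            bmat = -squareform(ratio)
            np.fill_diagonal(bmat, -bmat.sum(axis=1))
            x = bmat @ x / n
        cand = Ordination(x, history[-1], converged, history)
        if best is None or cand.stress < best.stress:
            best = cand
        if best.stress < 1e-12:
            break
    assert best is not None
    return best
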