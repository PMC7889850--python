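"""Pairwise dissimilarities: p-distance, Jaccard (binary) and Gower (dosage).

p-distance feeds the replicate-based locus QC, Jaccard is used for the
presence/absence fingerprint matrices and Gower for SNP dosage matrices
with missing entries (pairwise deletion, per-locus range scaling).
"""

from __future__ import annotations

import logging

import numpy as np

from .io_formats import MISSING, BinaryMarkerMatrix, DistanceMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


class PairwiseDeletionError(ValueError):
    """A sample pair shares no jointly observed locus."""


def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Proportion of positions at which two equal-length profiles differ."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("profiles must have length >= 1")
    return float(np.mean(a != b))


def jaccard_matrix(m: BinaryMarkerMatrix) -> DistanceMatrix:
    """Jaccard dissimilarity: 1 - shared/union over bands present in either.

    A pair of all-zero profiles has an undefined 0/0 ratio; it is assigned
    distance 0 and a warning is logged.
    """
    if m.n_samples < 2 or m.n_loci < 1:
        raise ValueError("need >= 2 samples and >= 1 locus")
    x = m.values.astype(np.float64)
    inter = x @ x.T
    band_counts = x.sum(axis=1)
    union = band_counts[:, None] + band_counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - inter / union
    double_zero = union == 0
    if double_zero.sum() > m.n_samples:  # off-diagonal hits
        logger.warning(
            "jaccard: %d sample pairs share no band at all; distance set to 0",
            int((double_zero.sum() - (band_counts == 0).sum()) // 2),
        )
    d[double_zero] = 0.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # kill float asymmetry noise
    return DistanceMatrix(list(m.sample_ids), d)


def gower_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """Range-scaled Gower distance on dosages with pairwise deletion.

    d(i,j) = mean over jointly observed loci of |x_il - x_jl| / r_l with
    r_l the observed dosage range of locus l; zero-range (monomorphic)
    loci are excluded from the mean.  A pair with no jointly observed
    locus raises :class:`PairwiseDeletionError`.
    """
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    x = g.values.astype(np.float64)
    obs = g.values != MISSING
    # per-locus observed range; all-missing loci get range 0 (excluded below)
    hi = np.where(obs, x, -np.inf).max(axis=0)
    lo = np.where(obs, x, np.inf).min(axis=0)
    rng = np.where(np.isfinite(hi) & np.isfinite(lo), hi - lo, 0.0)
    usable = rng > 0
    # joint-observation counts over all loci (for the error check) and over
    # usable loci (the Gower denominator)
    obs_f = obs.astype(np.float64)
    joint_all = obs_f @ obs_f.T
    iu, ju = np.triu_indices(g.n_samples, 1)
    bad = joint_all[iu, ju] == 0
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise PairwiseDeletionError(
            f"sample pair ({g.sample_ids[iu[k]]!r}, {g.sample_ids[ju[k]]!r}) "
            "shares no jointly non-missing locus"
        )
    obs_u = obs_f[:, usable]
    joint_u = obs_u @ obs_u.T
    scaled = np.where(obs, x, 0.0)[:, usable] / rng[usable]
    # sum over usable loci of |si - sj| restricted to jointly observed loci:
    # |si - sj| with missing zeroed is wrong where exactly one is missing,
    # so compute via the expansion trick on masked values.
    n = g.n_samples
    num = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(scaled[i] - scaled)  # (n, L_usable)
        mask = obs_u[i] * obs_u
        num[i] = (diff * mask).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / joint_u
    d[joint_u == 0] = 0.0  # jointly observed loci exist but all zero-range
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(g.sample_ids), d)
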