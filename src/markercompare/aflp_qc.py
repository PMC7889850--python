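"""Replicate-guided locus denoising and ordination-based outlier screening.

Stage 1 (:func:`greedy_replicate_filter`): blind replicates should carry a
profile identical to their source sample, so the sum of replicate-pair
p-distances measures scoring noise.  The filter makes a single sequential
pass over loci; a locus is dropped iff tentatively removing it strictly
lowers the current replicate distance sum (distances recomputed on the
reduced matrix, so the denominator shrinks with each removal).

Stage 2 (:func:`nmds_outlier_screen`): per primer combination, samples are
ordinated in two dimensions from Jaccard distances and tested against a
per-region coverage ellipse; individuals outside their ellipse in too many
combinations, or combinations with too many outside individuals, are
flagged for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import chi2

from .dissimilarity import jaccard_matrix
from .inference_stats import nmds
from .io_formats import BinaryMarkerMatrix, SampleMetadata

logger = logging.getLogger(__name__)


class DegenerateReplicatesError(ValueError):
    """Every locus mismatches in the replicates; the filter would empty the
    matrix.  Inspect the replicate links / scoring before re-running."""


@dataclass
class QcDecision:
    locus_id: str
    sum_if_removed: float | None  # None when removal was not evaluable
    accepted: bool
    sum_after: float


@dataclass
class QcLog:
    removed_locus_ids: list[str]
    decisions: list[QcDecision]
    initial_sum: float
    final_sum: float

    @property
    def distance_sum_trajectory(self) -> list[float]:
        return [d.sum_after for d in self.decisions]

    def to_dict(self) -> dict:
        return {
            "initial_sum": self.initial_sum,
            "final_sum": self.final_sum,
            "removed_locus_ids": list(self.removed_locus_ids),
            "decisions": [
                {
                    "locus": d.locus_id,
                    "sum_if_removed": d.sum_if_removed,
                    "accepted": d.accepted,
                    "sum_after": d.sum_after,
                }
                for d in self.decisions
            ],
        }


def _pair_indices(
    m: BinaryMarkerMatrix, pairs: Iterable[tuple[str, str]]
) -> list[tuple[int, int]]:
    out = []
    for a, b in pairs:
        if a not in m.sample_ids or b not in m.sample_ids:
            raise ValueError(f"replicate pair ({a!r}, {b!r}) not in matrix samples")
        out.append((m.sample_ids.index(a), m.sample_ids.index(b)))
    return out


def replicate_distance_sum(
    m: BinaryMarkerMatrix, pairs: Iterable[tuple[str, str]]
) -> float:
    """Sum of p-distances over replicate sample pairs (0 for no pairs)."""
    if m.n_loci < 1:
        raise ValueError("matrix has no loci")
    idx = _pair_indices(m, pairs)
    if not idx:
        logger.warning("replicate_distance_sum: empty pair set, returning 0")
        return 0.0
    total = 0.0
    for ia, ib in idx:
        total += float(np.mean(m.values[ia] != m.values[ib]))
    return total


def greedy_replicate_filter(
    m: BinaryMarkerMatrix, pairs: Iterable[tuple[str, str]], iterate: bool = False
) -> tuple[BinaryMarkerMatrix, QcLog]:
    """Single-pass greedy locus removal driven by the replicate distance sum.

    Loci are visited once in stored matrix order; after each accepted
    removal the distance sum is recomputed on the reduced matrix.  Ties
    keep the locus (strict inequality).  With ``iterate=True`` the pass is
    repeated until no locus is removed.
    """
    if m.n_loci < 2:
        raise ValueError("need >= 2 loci")
    idx = _pair_indices(m, pairs)
    if not idx:
        raise ValueError("greedy_replicate_filter needs a non-empty pair set")
    mism = np.stack(
        [(m.values[ia] != m.values[ib]).astype(np.int64) for ia, ib in idx]
    )  # (n_pairs, n_loci)
    alive = np.ones(m.n_loci, dtype=bool)
    per_pair = mism.sum(axis=1).astype(np.float64)
    n_alive = m.n_loci
    current = float(per_pair.sum() / n_alive)
    initial = current
    decisions: list[QcDecision] = []
    removed: list[str] = []

    while True:
        removed_this_pass = False
        for j, locus in enumerate(m.locus_ids):
            if not alive[j]:
                continue
            if n_alive == 1:
                if current > 0:
                    raise DegenerateReplicatesError(
                        "replicate filtering would remove every locus; "
                        "inspect the replicate links and scoring"
                    )
                decisions.append(QcDecision(locus, None, False, current))
                continue
            cand = float((per_pair - mism[:, j]).sum() / (n_alive - 1))
            accept = cand < current
            if accept:
                alive[j] = False
                per_pair -= mism[:, j]
                n_alive -= 1
                current = cand
                removed.append(locus)
                removed_this_pass = True
            decisions.append(QcDecision(locus, cand, accept, current))
        if not iterate or not removed_this_pass:
            break

    kept = [l for l, a in zip(m.locus_ids, alive) if a]
    filtered = m.subset_loci(kept)
    log = QcLog(removed, decisions, initial, current)
    logger.info(
        "replicate filter: removed %d of %d loci; distance sum %.6f -> %.6f",
        len(removed), m.n_loci, initial, current,
    )
    return filtered, log


# ---------------------------------------------------------------------------
# Ordination-based outlier screen
# ---------------------------------------------------------------------------


@dataclass
class EllipseParams:
    center: np.ndarray
    covariance: np.ndarray
    coverage: float

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        # tiny ridge keeps degenerate (coincident-point) regions solvable;
        # coincident points then land exactly on the center and stay inside
        ridge = 1e-9 * max(float(np.trace(self.covariance)), 1e-12)
        cov = self.covariance + ridge * np.eye(self.covariance.shape[0])
        inv = np.linalg.inv(cov)
        diff = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", diff, inv, diff)

    def contains(self, points: np.ndarray) -> np.ndarray:
        q = chi2.ppf(self.coverage, df=self.center.size)
        return self.mahalanobis_sq(points) <= q


@dataclass
class ScreenReport:
    excluded_individuals: list[str]
    excluded_combos: list[str]
    individual_outside_fraction: dict[str, float]
    combo_outside_fraction: dict[str, float]
    outside_flags: dict[str, dict[str, bool | None]]  # combo -> sample -> flag
    ellipses: dict[str, dict[str, EllipseParams]] = field(default_factory=dict)
    coverage: float = 0.90
    indiv_threshold: float = 0.5
    combo_threshold: float = 0.1

    def to_dict(self) -> dict:
        return {
            "coverage": self.coverage,
            "indiv_threshold": self.indiv_threshold,
            "combo_threshold": self.combo_threshold,
            "excluded_individuals": self.excluded_individuals,
            "excluded_combos": self.excluded_combos,
            "individual_outside_fraction": self.individual_outside_fraction,
            "combo_outside_fraction": self.combo_outside_fraction,
            "outside_flags": self.outside_flags,
        }


def _outside_fractions(
    outside_flags: dict[str, dict[str, bool | None]],
    samples: list[str],
    combos: Iterable[str],
) -> dict[str, float]:
    frac: dict[str, float] = {}
    for s in samples:
        flags = [outside_flags[c][s] for c in combos if outside_flags[c][s] is not None]
        frac[s] = (sum(flags) / len(flags)) if flags else 0.0
    return frac


def nmds_outlier_screen(
    matrices: Mapping[str, BinaryMarkerMatrix],
    meta: SampleMetadata,
    coverage: float = 0.90,
    indiv_threshold: float = 0.5,
    combo_threshold: float = 0.1,
    per_region: bool = True,
    seed: int = 0,
    nmds_restarts: int = 8,
) -> ScreenReport:
    """Flag outlier individuals and noisy primer combinations.

    Per combination: Jaccard distances -> 2-d NMDS -> per-region coverage
    ellipse (chi-square quantile, 2 df, on the region's sample covariance).
    An individual is outside iff outside its own region's ellipse.  With
    ``per_region=False`` one global ellipse over all samples is used.
    Individuals in regions with < 3 assessable members are marked
    unassessable (flag ``None``) and never counted as outside.

    Exclusion is two-phase: individuals are flagged first (outside in more
    than ``indiv_threshold`` of combinations), then combinations (more than
    ``combo_threshold`` of individuals outside); individual fractions are
    recomputed once over the surviving combinations.
    """
    combos = list(matrices)
    if not combos:
        raise ValueError("no primer-combination matrices given")
    samples = list(matrices[combos[0]].sample_ids)
    for c in combos[1:]:
        if set(matrices[c].sample_ids) != set(samples):
            raise ValueError(f"combo {c!r} covers a different sample set")

    outside_flags: dict[str, dict[str, bool | None]] = {}
    ellipses: dict[str, dict[str, EllipseParams]] = {}
    ss = np.random.SeedSequence(seed)
    for ci, combo in enumerate(combos):
        m = matrices[combo].subset_samples(samples)
        d = jaccard_matrix(m)
        ordn = nmds(
            d, k=2, restarts=nmds_restarts,
            seed=int(np.random.SeedSequence(seed, spawn_key=(ci,)).generate_state(1)[0]),
        )
        coords = {s: ordn.coordinates[i] for i, s in enumerate(samples)}
        flags: dict[str, bool | None] = {}
        ellipses[combo] = {}
        if per_region:
            groups: dict[str, list[str]] = {}
            for s in samples:
                groups.setdefault(meta.region[s], []).append(s)
        else:
            groups = {"__all__": list(samples)}
        for region, members in groups.items():
            pts = np.stack([coords[s] for s in members])
            if len(members) < 3:
                for s in members:
                    flags[s] = None
                continue
            ell = EllipseParams(pts.mean(axis=0), np.cov(pts, rowvar=False), coverage)
            ellipses[combo][region] = ell
            inside = ell.contains(pts)
            for s, ok in zip(members, inside):
                flags[s] = not bool(ok)
        outside_flags[combo] = flags

    indiv_frac = _outside_fractions(outside_flags, samples, combos)
    excluded_individuals = [s for s in samples if indiv_frac[s] > indiv_threshold]

    combo_frac: dict[str, float] = {}
    for combo in combos:
        flags = outside_flags[combo]
        assessable = [s for s in samples if flags[s] is not None]
        combo_frac[combo] = (
            sum(flags[s] for s in assessable) / len(assessable) if assessable else 0.0
        )
    excluded_combos = [c for c in combos if combo_frac[c] > combo_threshold]

    if excluded_combos:
        surviving = [c for c in combos if c not in excluded_combos]
        if surviving:
            indiv_frac = _outside_fractions(outside_flags, samples, surviving)
            excluded_individuals = [
                s for s in samples if indiv_frac[s] > indiv_threshold
            ]

    return ScreenReport(
        excluded_individuals=excluded_individuals,
        excluded_combos=excluded_combos,
        individual_outside_fraction=indiv_frac,
        combo_outside_fraction=combo_frac,
        outside_flags=outside_flags,
        ellipses=ellipses,
        coverage=coverage,
        indiv_threshold=indiv_threshold,
        combo_threshold=combo_threshold,
    )
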