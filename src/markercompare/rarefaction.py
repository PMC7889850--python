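"""Locus down-sampling experiment: how many SNP loci carry the full signal?

Loci are drawn without replacement within each replicate (the same locus
may recur across replicates).  At each step size the group-separation
statistic (Global R) and the correlation of the sub-sampled Gower matrix
with the full-matrix Gower distances (Mantel r) are recorded, with a
significance flag at alpha.  Degenerate draws — e.g. a sample pair left
with no jointly observed locus — become explicit not-applicable records
instead of aborting the sweep.  A reference overlay computed from a
matched dominant-marker matrix can be attached at its own locus count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dissimilarity import PairwiseDeletionError, gower_matrix
from .inference_stats import anosim, mantel
from .io_formats import DistanceMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class RarefactionRecord:
    step: int
    replicate: int
    global_R: float | None
    anosim_p: float | None
    mantel_r_vs_full: float | None
    mantel_p: float | None
    significant: bool | None
    reason: str | None = None  # set on not-applicable records

    @property
    def applicable(self) -> bool:
        return self.reason is None


@dataclass
class AflpOverlay:
    locus_count: int
    global_R: float
    anosim_p: float
    mantel_r: list[float]
    mantel_p: list[float]


@dataclass
class RarefactionResult:
    steps: list[int]
    records: list[RarefactionRecord]
    summaries: dict[int, dict[str, float]]
    aflp_overlay: AflpOverlay | None = None
    step_size: int = 50
    reps: int = 50
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "step_size": self.step_size,
            "reps": self.reps,
            "alpha": self.alpha,
            "seed": self.seed,
            "steps": self.steps,
            "records": [vars(r) for r in self.records],
            "summaries": {str(k): v for k, v in self.summaries.items()},
            "aflp_overlay": None
            if self.aflp_overlay is None
            else vars(self.aflp_overlay),
        }


def _record_rng(seed: int, step_index: int, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(step_index, replicate))
    return np.random.default_rng(ss)


def subsample_loci(g: GenotypeMatrix, n: int, seed: int | np.random.Generator) -> GenotypeMatrix:
    """Uniform random n-subset of loci without replacement, order preserved."""
    if not 1 <= n <= g.n_loci:
        raise ValueError(f"n must be in [1, {g.n_loci}], got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(g.n_loci, size=n, replace=False))
    return g.subset_loci_idx(idx)


def _evaluate_subsample(
    sub: GenotypeMatrix,
    groups: Mapping[str, str],
    full_dist: DistanceMatrix,
    step: int,
    replicate: int,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
) -> RarefactionRecord:
    try:
        d = gower_matrix(sub)
    except PairwiseDeletionError as exc:
        return RarefactionRecord(
            step, replicate, None, None, None, None, None,
            reason=f"no_shared_loci: {exc}",
        )
    seeds = rng.integers(0, 2**63 - 1, size=2)
    try:
        a = anosim(d, groups, n_perm=n_perm, seed=int(seeds[0]))
    except ValueError as exc:
        return RarefactionRecord(
            step, replicate, None, None, None, None, None,
            reason=f"anosim_degenerate: {exc}",
        )
    try:
        mt = mantel(d, full_dist, n_perm=n_perm, seed=int(seeds[1]))
        mr, mp = mt.r, mt.p_value
        sig = a.p_value <= alpha and mp <= alpha
    except ValueError as exc:
        return RarefactionRecord(
            step, replicate, a.global_R, a.p_value, None, None, None,
            reason=f"mantel_degenerate: {exc}",
        )
    return RarefactionRecord(step, replicate, a.global_R, a.p_value, mr, mp, sig)


def _summaries(records: list[RarefactionRecord], steps: Sequence[int]) -> dict:
    out: dict[int, dict[str, float]] = {}
    for s in steps:
        recs = [r for r in records if r.step == s and r.applicable]
        entry: dict[str, float] = {"n_applicable": float(len(recs))}
        if recs:
            for key in ("global_R", "mantel_r_vs_full"):
                vals = np.array([getattr(r, key) for r in recs], dtype=float)
                entry[f"{key}_mean"] = float(vals.mean())
                entry[f"{key}_sd"] = float(vals.std(ddof=1)) if len(recs) > 1 else 0.0
        out[s] = entry
    return out


def rarefaction_curves(
    g: GenotypeMatrix,
    groups: Mapping[str, str],
    step: int = 50,
    reps: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    n_perm: int = 999,
    extra_steps: Sequence[int] = (),
) -> RarefactionResult:
    """Run the full down-sampling sweep.

    Steps are ``step, 2*step, ... <= n_loci`` plus any ``extra_steps``
    (e.g. a matched reference locus count).  Each (step, replicate) record
    draws its loci from a dedicated seed substream, so any single record
    can be reproduced in isolation.
    """
    if step < 1 or reps < 1:
        raise ValueError("step and reps must be >= 1")
    if g.n_loci < step:
        raise ValueError(f"matrix has {g.n_loci} loci, fewer than step={step}")
    steps = sorted(
        set(range(step, g.n_loci + 1, step))
        | {s for s in extra_steps if 1 <= s <= g.n_loci}
    )
    full_dist = gower_matrix(g)
    records: list[RarefactionRecord] = []
    for si, s in enumerate(steps):
        for rep in range(reps):
            rng = _record_rng(seed, si, rep)
            sub = subsample_loci(g, s, rng)
            records.append(
                _evaluate_subsample(sub, groups, full_dist, s, rep, n_perm, alpha, rng)
            )
        na = sum(1 for r in records if r.step == s and not r.applicable)
        if na:
            logger.warning("step %d: %d of %d replicates not applicable", s, na, reps)
    return RarefactionResult(
        steps=steps,
        records=records,
        summaries=_summaries(records, steps),
        step_size=step,
        reps=reps,
        alpha=alpha,
        seed=seed,
    )


def aflp_overlay(
    aflp_dist: DistanceMatrix,
    aflp_groups: Mapping[str, str],
    g: GenotypeMatrix,
    n_loci: int,
    reps: int = 50,
    seed: int = 0,
    n_perm: int = 999,
    match: Mapping[str, str] | None = None,
) -> AflpOverlay:
    """Reference-marker overlay at a matched locus count.

    Computes Global R on the reference (AFLP-side) distance matrix and the
    distribution over ``reps`` subsamples of the Mantel correlation
    between that matrix and Gower distances of ``n_loci`` SNP loci.
    ``match`` maps reference labels to SNP sample ids (default: identity).
    """
    if n_loci > g.n_loci:
        raise ValueError(
            f"reference locus count {n_loci} exceeds SNP locus count {g.n_loci}"
        )
    mapping = dict(match) if match else {l: l for l in aflp_dist.labels}
    unmatched = [l for l in aflp_dist.labels if mapping.get(l) not in g.sample_ids]
    if unmatched:
        raise ValueError(f"reference samples without SNP partner: {unmatched}")
    g_matched = g.subset_samples([mapping[l] for l in aflp_dist.labels])
    # relabel SNP side with the reference labels so matrices align by label
    g_matched = GenotypeMatrix(
        list(aflp_dist.labels), list(g_matched.locus_ids), g_matched.values
    )
    a = anosim(aflp_dist, aflp_groups, n_perm=n_perm,
               seed=int(np.random.SeedSequence(seed, spawn_key=(0,)).generate_state(1)[0]))
    rs: list[float] = []
    ps: list[float] = []
    for rep in range(reps):
        rng = _record_rng(seed, 10**6, rep)
        sub = subsample_loci(g_matched, n_loci, rng)
        d = gower_matrix(sub)
        mt = mantel(aflp_dist, d, n_perm=n_perm,
                    seed=int(rng.integers(0, 2**63 - 1)))
        rs.append(mt.r)
        ps.append(mt.p_value)
    return AflpOverlay(
        locus_count=n_loci,
        global_R=a.global_R,
        anosim_p=a.p_value,
        mantel_r=rs,
        mantel_p=ps,
    )
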