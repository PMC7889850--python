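"""Paired synthetic dominant-fingerprint and SNP dosage datasets.

Regional allele frequencies follow the Balding–Nichols F-model: ancestral
frequencies are uniform on (0.05, 0.95) and each region draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so F controls between-region
differentiation.  From one :class:`LatentStructure` both marker types are
sampled for the same individuals (joined by ``match_key``), which makes
the cross-marker coherence of the downstream statistics testable.

Dominant bands are present with probability 1 - (1 - f)^2 (a band shows
whenever at least one of the two alleles carries it); every scored
fingerprint — originals and blind replicates alike — flips each locus
independently with probability epsilon, so a replicate pair mismatches at
a locus with probability 2*eps*(1-eps).  SNP dosages are Binomial(2, f)
with missing-completely-at-random dropout at rate m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (
    MISSING,
    BinaryMarkerMatrix,
    GenotypeMatrix,
    SampleMetadata,
)

N_PRIMER_COMBOS = 8  # round-robin combo tags, mirroring an 8-combination design


@dataclass
class SimulationParams:
    n_regions: int = 5
    n_per_region: int = 3
    n_loci_aflp: int = 500
    n_loci_snp: int = 5000
    F: float = 0.3
    epsilon: float = 0.05
    n_replicate_pairs: int = 3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_per_region < 1:
            raise ValueError("need >= 1 region and >= 1 individual per region")
        if self.n_loci_aflp < 1 or self.n_loci_snp < 1:
            raise ValueError("need >= 1 locus for each marker type")
        if not 0.0 <= self.F < 1.0:
            raise ValueError(f"F must be in [0, 1), got {self.F}")
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError(f"epsilon must be in [0, 0.5], got {self.epsilon}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.n_replicate_pairs > self.n_regions * self.n_per_region:
            raise ValueError("more replicate pairs than individuals")
        if self.n_replicate_pairs < 0:
            raise ValueError("n_replicate_pairs must be >= 0")

    @property
    def n_individuals(self) -> int:
        return self.n_regions * self.n_per_region

    def region_names(self) -> list[str]:
        return [f"R{r + 1}" for r in range(self.n_regions)]

    def individual_ids(self) -> list[str]:
        return [
            f"R{r + 1}_i{i + 1}"
            for r in range(self.n_regions)
            for i in range(self.n_per_region)
        ]


@dataclass
class LatentStructure:
    ancestral_freq: dict[str, np.ndarray]  # marker type -> (n_loci,)
    region_freq: dict[str, np.ndarray]  # marker type -> (n_regions, n_loci)
    params: SimulationParams

    def __post_init__(self) -> None:
        for key, p in self.ancestral_freq.items():
            f = self.region_freq[key]
            if ((p < 0) | (p > 1)).any() or ((f < 0) | (f > 1)).any():
                raise ValueError(f"frequencies outside [0,1] for {key!r}")


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(params.seed, spawn_key=(stream,))
    )


def _draw_freqs(
    rng: np.random.Generator, n_regions: int, n_loci: int, F: float
) -> tuple[np.ndarray, np.ndarray]:
    p = rng.uniform(0.05, 0.95, size=n_loci)
    if F == 0.0:
        f = np.tile(p, (n_regions, 1))
    else:
        a = p * (1.0 - F) / F
        b = (1.0 - p) * (1.0 - F) / F
        f = rng.beta(a, b, size=(n_regions, n_loci))
    return p, f


def simulate_structure(params: SimulationParams) -> LatentStructure:
    """Draw ancestral and per-region allele frequencies for both marker types."""
    rng = _rng(params, 0)
    p_aflp, f_aflp = _draw_freqs(rng, params.n_regions, params.n_loci_aflp, params.F)
    p_snp, f_snp = _draw_freqs(rng, params.n_regions, params.n_loci_snp, params.F)
    return LatentStructure(
        ancestral_freq={"aflp": p_aflp, "snp": p_snp},
        region_freq={"aflp": f_aflp, "snp": f_snp},
        params=params,
    )


def simulate_aflp(
    ls: LatentStructure, params: SimulationParams
) -> tuple[BinaryMarkerMatrix, SampleMetadata]:
    """Sample a scored fingerprint table with blind replicates.

    Each individual's true band profile is Bernoulli(1 - (1 - f)^2); blind
    replicates copy the true profile of a randomly chosen source
    individual; every scored row then flips each locus with probability
    epsilon.  Loci get round-robin combo tags across 8 combinations.
    """
    rng = _rng(params, 1)
    n_loci = params.n_loci_aflp
    ids = params.individual_ids()
    band_prob = 1.0 - (1.0 - ls.region_freq["aflp"]) ** 2
    true = np.empty((params.n_individuals, n_loci), dtype=np.int8)
    row = 0
    for r in range(params.n_regions):
        for _ in range(params.n_per_region):
            true[row] = rng.random(n_loci) < band_prob[r]
            row += 1
    rep_sources = rng.choice(
        params.n_individuals, size=params.n_replicate_pairs, replace=False
    )
    all_ids = list(ids) + [f"{ids[s]}_rep" for s in rep_sources]
    profiles = np.vstack([true] + [true[s][None, :] for s in rep_sources])
    if params.epsilon > 0:
        flips = rng.random(profiles.shape) < params.epsilon
        profiles = np.where(flips, 1 - profiles, profiles).astype(np.int8)
    locus_ids = [f"A{j + 1}" for j in range(n_loci)]
    primer_combo = {
        l: f"combo{(j % N_PRIMER_COMBOS) + 1}" for j, l in enumerate(locus_ids)
    }
    matrix = BinaryMarkerMatrix(all_ids, locus_ids, profiles, primer_combo)
    region = {}
    replicate_of = {}
    match_key = {}
    for r in range(params.n_regions):
        for i in range(params.n_per_region):
            sid = f"R{r + 1}_i{i + 1}"
            region[sid] = f"R{r + 1}"
            match_key[sid] = sid
    for s in rep_sources:
        rep_id = f"{ids[s]}_rep"
        region[rep_id] = region[ids[s]]
        replicate_of[rep_id] = ids[s]
    meta = SampleMetadata(all_ids, region, replicate_of, match_key)
    return matrix, meta


def simulate_snp(
    ls: LatentStructure, params: SimulationParams
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Sample a diploid dosage matrix with MCAR missingness.

    Individuals carry the same ids/match_keys as the paired fingerprint
    simulation from the same :class:`LatentStructure`.
    """
    rng = _rng(params, 2)
    n_loci = params.n_loci_snp
    ids = params.individual_ids()
    dosage = np.empty((params.n_individuals, n_loci), dtype=np.int8)
    row = 0
    for r in range(params.n_regions):
        for _ in range(params.n_per_region):
            dosage[row] = rng.binomial(2, ls.region_freq["snp"][r]).astype(np.int8)
            row += 1
    if params.missing_rate > 0:
        drop = rng.random(dosage.shape) < params.missing_rate
        dosage[drop] = MISSING
    locus_ids = [f"S{j + 1}" for j in range(n_loci)]
    matrix = GenotypeMatrix(list(ids), locus_ids, dosage)
    region = {sid: f"R{r + 1}"
              for r in range(params.n_regions)
              for sid in [f"R{r + 1}_i{i + 1}" for i in range(params.n_per_region)]}
    match_key = {sid: sid for sid in ids}
    meta = SampleMetadata(list(ids), region, {}, match_key)
    return matrix, meta
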