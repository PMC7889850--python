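import numpy as np
import pytest

from markercompare.io_formats import BinaryMarkerMatrix, GenotypeMatrix, SampleMetadata
from markercompare.synthetic_data import (
    SimulationParams,
    simulate_aflp,
    simulate_snp,
    simulate_structure,
)


@pytest.fixture
def small_binary_matrix() -> BinaryMarkerMatrix:
    rng = np.random.default_rng(42)
    values = rng.integers(0, 2, size=(5, 8))
    return BinaryMarkerMatrix(
        sample_ids=[f"s{i}" for i in range(5)],
        locus_ids=[f"L{j}" for j in range(8)],
        values=values,
        primer_combo={f"L{j}": f"c{j % 2}" for j in range(8)},
    )


@pytest.fixture
def small_genotype_matrix() -> GenotypeMatrix:
    rng = np.random.default_rng(7)
    values = rng.integers(0, 3, size=(6, 10)).astype(np.int8)
    values[rng.random(values.shape) < 0.15] = -1
    return GenotypeMatrix(
        sample_ids=[f"g{i}" for i in range(6)],
        locus_ids=[f"S{j}" for j in range(10)],
        values=values,
    )


@pytest.fixture
def paired_simulation():
    """Moderately structured paired datasets shared across tests."""
    params = SimulationParams(
        n_regions=4,
        n_per_region=4,
        n_loci_aflp=300,
        n_loci_snp=1500,
        F=0.3,
        epsilon=0.03,
        n_replicate_pairs=3,
        missing_rate=0.1,
        seed=11,
    )
    ls = simulate_structure(params)
    aflp, aflp_meta = simulate_aflp(ls, params)
    snp, snp_meta = simulate_snp(ls, params)
    return params, ls, (aflp, aflp_meta), (snp, snp_meta)


def random_distance_matrix(rng: np.random.Generator, n: int):
    """Random symmetric zero-diagonal matrix from points in the plane plus noise."""
    pts = rng.normal(size=(n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    noise = rng.uniform(0, 0.2, size=(n, n))
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0)
    return d + noise
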