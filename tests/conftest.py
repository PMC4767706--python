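import numpy as np
import pytest

from genotax.io import GenomeRecord, RelatednessMatrix
from genotax.synthetic import PlantedDesign, PlantedMatrixDesign, simulate_matrix


@pytest.fixture
def chain3() -> RelatednessMatrix:
    """Three points where links are not transitive at T=0.2: a-b, b-c close, a-c far."""
    dm = np.array([[0.0, 0.1, 0.5],
                   [0.1, 0.0, 0.15],
                   [0.5, 0.15, 0.0]])
    return RelatednessMatrix(["a", "b", "c"], dm, scale="distance")


@pytest.fixture
def planted_matrix():
    """Small planted 3-group similarity matrix with clean separation."""
    design = PlantedMatrixDesign(
        structure=[[[2], [1]], [[2, 1]], [[1], [1], [1]]],
        levels={"subspecies": 92.0, "species": 75.0, "group": 45.0, "between": 20.0},
        noise=1.0)
    matrix, truths = simulate_matrix(design, seed=11)
    return matrix, truths


@pytest.fixture
def tiny_design() -> PlantedDesign:
    return PlantedDesign(k_groups=2, species_per_group=1, strains_per_species=2,
                         genome_length=6000, rate_strain=0.01, rate_species=0.05,
                         rate_group=0.2, core_families=6,
                         group_exclusive_families=2, strain_exclusive_mean=1.5,
                         paralog_rate=0.15, family_length=(60, 120))


@pytest.fixture
def random_distance_matrix():
    rng = np.random.default_rng(42)

    def make(n: int, seed: int | None = None) -> RelatednessMatrix:
        r = rng if seed is None else np.random.default_rng(seed)
        vals = r.uniform(0.05, 1.0, size=(n, n))
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        return RelatednessMatrix([f"g{i}" for i in range(n)], vals, scale="distance")

    return make


@pytest.fixture
def nucleotide_record() -> GenomeRecord:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    return GenomeRecord("toy", [("c1", seq)], alphabet="nucleotide")
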