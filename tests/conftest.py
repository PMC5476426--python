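"""Shared fixtures: toy genomes, homology maps, and polymer populations.

The polymer populations are session-scoped because they are by far the most
expensive objects in the suite; every test that needs an ensemble shares
them.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridhic.contacts import normalize_matrix
from hybridhic.genome import (
    ChromosomeSpec,
    HybridGenomeSpec,
    build_bin_index,
    call_homologous_bins,
)
from hybridhic.polymer import (
    PolymerConfig,
    build_chain_specs,
    population_to_contact_matrix,
    simulate_population,
)
from hybridhic.synth import make_toy_hybrid, rabl_toy_world


@pytest.fixture(scope="session")
def tiny_genome() -> HybridGenomeSpec:
    """Two chromosomes per parent, a handful of bins each."""
    return HybridGenomeSpec(
        [
            ChromosomeSpec("c1", 1, 160_000, 70_000),
            ChromosomeSpec("c2", 1, 96_000, 40_000),
            ChromosomeSpec("u1", 2, 160_000, 70_000),
            ChromosomeSpec("u2", 2, 96_000, 40_000),
        ]
    )


@pytest.fixture(scope="session")
def tiny_index(tiny_genome):
    return build_bin_index(tiny_genome, 32_000)


@pytest.fixture(scope="session")
def polymer_world():
    genome, table, registry = make_toy_hybrid(rabl_toy_world())
    index = build_bin_index(genome, 32_000)
    hmap = call_homologous_bins(table, index)
    return {"genome": genome, "table": table, "index": index, "hmap": hmap}


def _population(world, size_multiplier: float, n_structures: int, seed: int):
    config = PolymerConfig(
        bead_size=8_000,
        n_structures=n_structures,
        size_multiplier=size_multiplier,
        seed=seed,
    )
    chains = build_chain_specs(world["genome"], config)
    return simulate_population(chains, config)


@pytest.fixture(scope="session")
def polymer_population(polymer_world):
    """Baseline-size ensemble, 1000 structures."""
    return _population(polymer_world, 1.0, 1000, seed=11)


@pytest.fixture(scope="session")
def polymer_population_small(polymer_world):
    """100-structure ensemble for validity/determinism checks."""
    return _population(polymer_world, 1.0, 100, seed=23)


@pytest.fixture(scope="session")
def polymer_normalized(polymer_world, polymer_population):
    matrix = population_to_contact_matrix(polymer_population, polymer_world["index"])
    return normalize_matrix(matrix)


@pytest.fixture(scope="session")
def small_nucleus_medians(polymer_world):
    """DCEN_ARM bootstrap medians at size multipliers 0.8 and 0.64."""
    from hybridhic.proximity import ControlLevel, ExclusionPolicy, bootstrap_genomic_proximity

    policy = ExclusionPolicy.genome_wide()
    out = {}
    for mult in (0.8, 0.64):
        pop = _population(polymer_world, mult, 1000, seed=11)
        norm = normalize_matrix(population_to_contact_matrix(pop, polymer_world["index"]))
        dist = bootstrap_genomic_proximity(
            norm, polymer_world["hmap"], ControlLevel.DCEN_ARM, policy, seed=5
        )
        out[mult] = dist.median
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
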