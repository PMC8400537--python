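"""Shared fixtures and toy-data builders for the hybridscan test-suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hybridscan.genotypes import GenotypeMatrix, SpeciesMap
from hybridscan.simulate import (
    HybridSpec,
    SimulationConfig,
    simulate_dataset,
    three_species_model,
)


def make_gm(calls, specimens=None, loci=None, depth=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list of calls
    (rows = specimens, columns = sites; -1 missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_spec, n_sites = calls.shape
    specimens = specimens or [f"s{i}" for i in range(n_spec)]
    loci = loci or ["L1"] * n_sites
    sites = pd.DataFrame(
        {
            "locus": loci,
            "pos": _positions(loci),
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
        }
    )
    return GenotypeMatrix(
        specimens=list(specimens),
        sites=sites,
        calls=calls,
        depth=None if depth is None else np.asarray(depth, dtype=float),
    )


def _positions(loci):
    pos, counter = [], {}
    for lo in loci:
        counter[lo] = counter.get(lo, 0) + 1
        pos.append(counter[lo])
    return pos


def species_map_for(gm: GenotypeMatrix, assignment: dict[str, list[str]],
                    outgroup: str | None = None,
                    queries: tuple[str, ...] = ()) -> SpeciesMap:
    species, roles = {}, {}
    for sp, members in assignment.items():
        for m in members:
            species[m] = sp
            roles[m] = (
                "outgroup" if sp == outgroup
                else "query" if m in queries
                else "reference"
            )
    return SpeciesMap(species=species, roles=roles)


# ---------------------------------------------------------------------------
# one moderately sized simulated system shared by several test modules

@pytest.fixture(scope="session")
def hybrid_dataset():
    """3 diverged species (4 specimens each) + outgroup + one planted F1."""
    model = three_species_model(150_000, 300_000, 600_000)
    cfg = SimulationConfig(
        species_model=model,
        n_specimens_per_species={"P1": 4, "P2": 4, "P3": 4, "OUT": 2},
        n_loci=80,
        locus_length=1000,
        mutation_rate=3e-8,
        hybrids=[HybridSpec("hyb1", "P1", "P2")],
        outgroup="OUT",
        seed=20_260_927,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def hybrid_gm(hybrid_dataset):
    return hybrid_dataset.genotype_matrix()


@pytest.fixture(scope="session")
def hybrid_species_map(hybrid_dataset):
    return hybrid_dataset.species_map()
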