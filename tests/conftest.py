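"""Shared fixtures: small hand-built matrices and module-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

import popgen
from popgen import GenotypeMatrix, SimulationConfig


@pytest.fixture
def tiny_gm() -> GenotypeMatrix:
    """5 individuals, 2 loci; locus B has a missing call and 3 alleles."""
    calls = [
        [("150", "150"), ("200", "202")],
        [("150", "152"), ("200", "200")],
        [("150", "152"), ("202", "204")],
        [("152", "152"), None],
        [("150", "152"), ("200", "204")],
    ]
    return GenotypeMatrix.from_calls(
        [f"s{i}" for i in range(5)], ["locA", "locB"], calls)


@pytest.fixture(scope="session")
def structured_pop():
    """Two well-separated clusters with planted truth (module-wide reuse)."""
    cfg = SimulationConfig(n_clusters=2, cluster_sizes=[100, 100], n_loci=26,
                           alleles_per_locus=4, fst_target=0.3,
                           inbreeding_profile=0.0, migrant_fraction=0.0, seed=42)
    return popgen.simulate_structured_pop(cfg)


@pytest.fixture(scope="session")
def lowdiv_freqs():
    """Allele frequencies of a low-diversity 26-locus panel (He ~ 0.35)."""
    gm, _ = popgen.simulate_structured_pop(SimulationConfig(seed=44))
    return popgen.allele_frequencies(gm)


@pytest.fixture(scope="session")
def panmictic_pop():
    """Single random-mating population, no structure, no inbreeding."""
    cfg = SimulationConfig(n_clusters=1, cluster_sizes=[100], n_loci=26,
                           alleles_per_locus=4, fst_target=0.0,
                           inbreeding_profile=0.0, migrant_fraction=0.0, seed=43)
    return popgen.simulate_structured_pop(cfg)
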