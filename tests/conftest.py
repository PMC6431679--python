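"""Shared fixtures: small simulated studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from subgenomics.simdata import EvolutionParams, simulate_evolution
from subgenomics.simdata.hits import (
    make_cross_species_hits,
    make_outgroup,
    make_outgroup_hits,
)

EVENT_COUNTS = {"C": 10, "iT": 5, "Dup": 5, "Del": 5, "A": 5}


@pytest.fixture(scope="session")
def event_params() -> EvolutionParams:
    """~2000-gene genomes carrying a known rearrangement spectrum and no
    fractionation noise."""
    return EvolutionParams(
        n_chromosome_pairs=2, genes_per_chromosome=500,
        deletion_prob_dominant=0.0, deletion_prob_subdominant=0.0,
        rearrangement_counts=dict(EVENT_COUNTS), seed=42,
    )


@pytest.fixture(scope="session")
def event_study(event_params):
    genome_r, genome_m, truth = simulate_evolution(event_params)
    rng = np.random.default_rng(1_042)
    hits = make_cross_species_hits(genome_r, genome_m, rng)
    outgroup = make_outgroup(event_params)
    hits_r_out = make_outgroup_hits(genome_r, outgroup, rng)
    hits_m_out = make_outgroup_hits(genome_m, outgroup, rng)
    return {
        "params": event_params, "genome_r": genome_r, "genome_m": genome_m,
        "truth": truth, "hits": hits, "outgroup": outgroup,
        "hits_r_out": hits_r_out, "hits_m_out": hits_m_out,
    }


@pytest.fixture(scope="session")
def quiet_params() -> EvolutionParams:
    """Small genomes with neither deletions nor rearrangements."""
    return EvolutionParams(
        n_chromosome_pairs=2, genes_per_chromosome=300,
        deletion_prob_dominant=0.0, deletion_prob_subdominant=0.0,
        rearrangement_counts={}, seed=7,
    )


@pytest.fixture(scope="session")
def quiet_study(quiet_params):
    genome_r, genome_m, truth = simulate_evolution(quiet_params)
    hits = make_cross_species_hits(genome_r, genome_m,
                                   np.random.default_rng(77))
    return {"params": quiet_params, "genome_r": genome_r,
            "genome_m": genome_m, "truth": truth, "hits": hits}


@pytest.fixture(scope="session")
def default_params() -> EvolutionParams:
    """Defaults (asymmetric fractionation on) at reduced chromosome count."""
    return EvolutionParams(n_chromosome_pairs=4, genes_per_chromosome=500,
                           seed=11)


@pytest.fixture(scope="session")
def default_study(default_params):
    genome_r, genome_m, truth = simulate_evolution(default_params)
    return {"params": default_params, "genome_r": genome_r,
            "genome_m": genome_m, "truth": truth}
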