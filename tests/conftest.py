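"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from methylscope.motifs import MethSite, Motif
from methylscope.pileup import call_methylation
from methylscope.simulate import (
    MotifSpec,
    SimulationConfig,
    generate_genome,
    simulate_pileup,
)

GATC = Motif("GATC", (MethSite(1, "6mA"),))


@pytest.fixture(scope="session")
def gatc_sim():
    """200 kb genome, 500 planted GATC, p_site=0.98, coverage 100."""
    config = SimulationConfig(
        genome_length=200_000,
        seed=20_240_501,
        motif_specs=[MotifSpec(GATC, planted_count=500, p_site=0.98, p_read=0.9)],
        coverage=100,
        p_fail=0.05,
        p_diff=0.01,
    )
    genome, truth = generate_genome(config)
    records = simulate_pileup(genome, truth, config)
    calls = call_methylation(records)
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "records": records,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def ambiguity_sim():
    """50 kb genome with planted GATC and a strong G->A strand miscall rate."""
    from methylscope.simulate import simulate_strand_counts

    config = SimulationConfig(
        genome_length=50_000,
        seed=77,
        motif_specs=[MotifSpec(GATC, planted_count=200, p_site=0.98, p_read=0.9)],
        coverage=100,
        ambiguity_error_rate=0.5,
    )
    genome, truth = generate_genome(config)
    records = simulate_pileup(genome, truth, config)
    calls = call_methylation(records)
    counts = simulate_strand_counts(genome, truth, config)
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "calls": calls,
        "counts": counts,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
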