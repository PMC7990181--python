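"""Shared fixtures: a toy reference, cohort factories, seeded generators."""

from __future__ import annotations

import numpy as np
import pytest

from evorisk.genomic_io import ReferenceGenome
from evorisk.synthetic_cohort import (
    ClinicalVarSpec,
    DriverSpec,
    RatePriors,
    SimulationConfig,
    simulate_cohort,
)

# one shared toy genome spec so the module-level genome cache is effective
CONTIGS = {"chr1": 700_000, "chr2": 700_000}
GENOME_SEED = 0


def base_sim_config(**overrides) -> SimulationConfig:
    """A small but fully featured simulation config for tests."""
    defaults = dict(
        n_samples=100,
        contigs=dict(CONTIGS),
        rates=RatePriors(snv_rate=3.0, cna_rate=0.4, sv_rate=0.3, cna_lg_frac=0.4),
        drivers=[
            DriverSpec("DRV1", "chr1", 10_000, 20_000, mut_prob=0.3, rate_multipliers={"snv": 1.5}),
            DriverSpec("DRV2", "chr2", 50_000, 60_000, mut_prob=0.2),
        ],
        clinical=[
            ClinicalVarSpec("tumor_free", kind="binary", p=0.5),
            ClinicalVarSpec("age", kind="continuous", mean=0.0, sd=1.0),
            ClinicalVarSpec("stage", kind="categorical", levels=("i", "ii", "iii")),
        ],
        beta_true={"z_snv": 1.0, "tumor_free": -0.8},
        seed=3,
        genome_seed=GENOME_SEED,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(base_sim_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_genome():
    """Handcrafted genome where every position's context is known by eye."""
    return ReferenceGenome({"chrA": "ACGTACGTACGTACGTACGT", "chrB": "ACNTAGGTCCAT"})


def aggregate_columns(fm):
    """Feature columns without the 96 trinucleotide classes (fast benchmarks)."""
    return [c for c in fm.features if "[" not in c]
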