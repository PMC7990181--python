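"""Canonical synthetic benchmarks used by the acceptance suite.

Each builder returns plain package objects so the experiments can be rerun
from scratch under any seed: a mixed-hazard cohort whose evolutionary share
of the log-hazard variance is configurable, and a permuted-feature control
cohort for the "predictions collapse to chance" check.
"""

from __future__ import annotations

import numpy as np

from . import selection_pipeline as sp
from .synthetic_cohort import (
    ClinicalVarSpec,
    DriverSpec,
    RatePriors,
    SimulationConfig,
    simulate_cohort,
)
from .workflow import attribution_runs, extract_features, outcome_arrays

#: shared toy reference so the genome cache is effective across benchmark runs
BENCHMARK_CONTIGS = {"chr1": 700_000, "chr2": 700_000}
BENCHMARK_GENOME_SEED = 0


def mixed_hazard_config(
    n_samples: int,
    evolutionary_share: float,
    seed: int,
    n_drivers: int = 2,
) -> SimulationConfig:
    """Cohort whose hazard splits between phenotype and clinical covariates.

    ``evolutionary_share`` s in [0, 1] scales the phenotype (z_snv, z_cna)
    coefficients by sqrt(s) and the clinical ones by sqrt(1 - s), so s is
    the share of generative log-hazard variance carried by mutational
    phenotypes.
    """
    s = float(evolutionary_share)
    if not 0.0 <= s <= 1.0:
        raise ValueError("evolutionary_share must be in [0, 1]")
    drivers = [
        DriverSpec(
            f"DRV{i + 1}",
            "chr1" if i % 2 == 0 else "chr2",
            10_000 + 30_000 * (i // 2),
            20_000 + 30_000 * (i // 2),
            mut_prob=0.25,
            rate_multipliers={"snv": 1.5} if i == 0 else {},
        )
        for i in range(n_drivers)
    ]
    return SimulationConfig(
        n_samples=n_samples,
        contigs=dict(BENCHMARK_CONTIGS),
        rates=RatePriors(snv_rate=3.0, cna_rate=0.4, sv_rate=0.3, cna_lg_frac=0.4),
        drivers=drivers,
        clinical=[
            ClinicalVarSpec("tumor_free", kind="binary", p=0.5),
            ClinicalVarSpec("age", kind="continuous", mean=0.0, sd=1.0),
        ],
        beta_true={
            "z_snv": 1.5 * np.sqrt(s),
            "z_cna": 0.9 * np.sqrt(s),
            "tumor_free": -1.6 * np.sqrt(1.0 - s),
            "age": 0.9 * np.sqrt(1.0 - s),
        },
        seed=seed,
        genome_seed=BENCHMARK_GENOME_SEED,
    )


def aggregate_feature_names(fm) -> list[str]:
    """Candidate columns without the 96 trinucleotide classes (fast benchmarks)."""
    return [c for c in fm.features if "[" not in c]


def build_matrix(config: SimulationConfig, endpoint: str = "OS", aggregates_only: bool = True):
    """Simulate, extract and assemble; returns (FeatureMatrix, aligned records)."""
    cohort = simulate_cohort(config)
    fm, records = extract_features(
        cohort.variants,
        cohort.trees,
        cohort.genome,
        config.driver_catalog(),
        cohort.clinical,
        cohort.outcomes[endpoint],
        edge_years=config.edge_years,
    )
    if aggregates_only:
        fm = fm.select(aggregate_feature_names(fm))
    return fm, records


def fraction_estimate(
    n_samples: int,
    evolutionary_share: float,
    seed: int,
    outer_repeats: int = 2,
    max_k: int = 3,
):
    """End-to-end fraction(evolutionary) estimate for one benchmark cohort."""
    config = mixed_hazard_config(n_samples, evolutionary_share, seed)
    fm, records = build_matrix(config)
    sel = sp.SelectionConfig(outer_repeats=outer_repeats, max_k=max_k, seed=seed)
    _, fractions = attribution_runs(fm, records, sel)
    return fractions


def permuted_pipeline_mean_ci(seed: int, n_samples: int = 300) -> tuple[float, int]:
    """Mean held-out CI (percent) of the full two-loop l0 pipeline after
    permuting every feature column across samples.

    The cohort carries several genuine hazard effects and ~40 candidate
    features; the permutation breaks all feature-outcome association, so the
    result should sit near 50%.  Returns ``(mean CI %, n features)``.
    """
    config = mixed_hazard_config(n_samples, 0.5, seed, n_drivers=15)
    config.clinical.append(ClinicalVarSpec("stage", kind="categorical", levels=("i", "ii", "iii")))
    fm, records = build_matrix(config)
    y, delta = outcome_arrays(records)
    # the permutation is redrawn per replicate (each replicate = one 3-fold
    # outer CV on freshly permuted columns) so replicate averaging also
    # averages over the permutation draw
    cis = []
    for rep in range(5):
        sel = sp.SelectionConfig(outer_repeats=1, outer_folds=3, max_k=5, seed=seed * 31 + rep)
        result = sp.permutation_control(fm, y, delta, sel)
        cis.append(result.mean_ci)
    return 100.0 * float(np.mean(cis)), fm.values.shape[1]
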