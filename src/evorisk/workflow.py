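"""End-to-end glue: cohort I/O, feature extraction and attribution runs.

These helpers back the CLI and keep tests/acceptance scripts terse; every
piece of statistics lives in the dedicated modules.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_features as af
from . import evolutionary_features as ef
from . import genomic_io as gio
from . import risk_attribution as ra
from . import selection_pipeline as sp
from .synthetic_cohort import SimulatedCohort


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write a simulated cohort as plain-text artifacts.

    Layout: ``genome.fa``, ``vcf/<sample>.vcf``, ``trees/<sample>.json``,
    ``clinical.tsv``, ``outcomes.tsv``, ``ground_truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    cohort.genome.to_fasta(outdir / "genome.fa")
    contigs = {name: len(seq) for name, seq in cohort.genome.contigs.items()}
    for sample, records in cohort.variants.items():
        gio.write_vcf(outdir / "vcf" / f"{sample}.vcf", records, contigs=contigs)
        gio.write_clone_tree(outdir / "trees" / f"{sample}.json", cohort.trees[sample], sample)
    gio.write_clinical(outdir / "clinical.tsv", cohort.clinical)
    gio.write_outcomes(outdir / "outcomes.tsv", cohort.outcomes)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth.to_dict(), fh, indent=1)


def read_cohort_dir(indir):
    """Read back a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    genome = gio.ReferenceGenome.from_fasta(indir / "genome.fa")
    variants = {}
    trees = {}
    for vcf_path in sorted((indir / "vcf").glob("*.vcf")):
        sample = vcf_path.stem
        variants[sample] = gio.read_vcf(vcf_path, sample, reference=genome)
        trees[sample] = gio.read_clone_tree(indir / "trees" / f"{sample}.json")
    clinical = gio.read_clinical(indir / "clinical.tsv")
    outcomes = {ep: gio.read_outcomes(indir / "outcomes.tsv", ep) for ep in gio.ENDPOINTS}
    return genome, variants, trees, clinical, outcomes


def extract_features(
    variants: dict,
    trees: dict,
    genome: gio.ReferenceGenome,
    catalog: af.DriverCatalog,
    clinical: gio.ClinicalTable,
    outcomes: list,
    snp_mask=None,
    edge_years: float = 10.0,
):
    """Run the full feature-extraction stage for one endpoint.

    Returns the assembled, tagged :class:`FeatureMatrix` and the aligned
    outcome records (inner join on sample id).
    """
    evo_rows = {
        s: ef.sample_features(v, trees.get(s), genome, snp_mask=snp_mask, edge_years=edge_years)
        for s, v in variants.items()
    }
    evo = pd.DataFrame.from_dict(evo_rows, orient="index")
    evo.index.name = "sample"
    driver = af.driver_features(variants, catalog, edge_years=edge_years,
                               contigs=set(genome.contigs))
    clin = af.encode_clinical(clinical)
    return af.assemble_matrix(evo, driver, clin, outcomes)


def outcome_arrays(records):
    """(y, delta) arrays from aligned survival records."""
    return (
        np.asarray([r.y for r in records], dtype=float),
        np.asarray([r.delta for r in records], dtype=int),
    )


def attribution_runs(
    matrix: af.FeatureMatrix,
    records,
    config: sp.SelectionConfig,
    model: str = "l0",
    feature_subset=None,
):
    """Run the three feature-set experiments and compute the fraction metrics.

    The three runs (evolutionary-only, evolutionary+driver, full) share
    ``config.seed`` and therefore identical outer splits per replicate.
    ``feature_subset`` optionally restricts the candidate columns (applied
    before class tagging subsets) to keep small benchmarks fast.
    """
    if feature_subset is not None:
        matrix = matrix.select([c for c in feature_subset if c in matrix.features])
    y, delta = outcome_arrays(records)
    runs = {}
    for label, classes in (
        ("evolutionary", ("evolutionary",)),
        ("genomic", ("evolutionary", "driver")),
        ("full", ("evolutionary", "driver", "clinical")),
    ):
        sub = matrix.subset(classes)
        runs[label] = sp.two_loop_cv(sub, y, delta, config, model=model)
    fractions = ra.fraction_metrics(runs["evolutionary"], runs["genomic"], runs["full"])
    return runs, fractions
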