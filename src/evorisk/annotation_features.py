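"""Driver-gene mutation-rate features, clinical encoding and matrix assembly."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .genomic_io import ClinicalTable, SurvivalRecord, ValidationError, VariantRecord

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("evolutionary", "driver", "clinical")


@dataclass
class DriverCatalog:
    """Named genomic intervals of known cancer genes (1-based inclusive)."""

    intervals: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self) -> None:
        for name, ivs in self.intervals.items():
            for chrom, start, end in ivs:
                if end < start or start < 1:
                    raise ValidationError(f"driver {name!r}: invalid interval {chrom}:{start}-{end}")

    @classmethod
    def from_tsv(cls, path) -> "DriverCatalog":
        """Read a BED-like TSV with columns chrom, start, end, name (1-based inclusive)."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "name"])
        intervals: dict[str, list[tuple[str, int, int]]] = {}
        for _, row in df.iterrows():
            intervals.setdefault(str(row["name"]), []).append(
                (str(row["chrom"]), int(row["start"]), int(row["end"]))
            )
        return cls(intervals)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\n")
            for name in sorted(self.intervals):
                for chrom, start, end in self.intervals[name]:
                    fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")

    @property
    def contigs(self) -> set[str]:
        return {chrom for ivs in self.intervals.values() for chrom, _, _ in ivs}


@dataclass
class FeatureMatrix:
    """Samples x features with a class tag per feature.

    ``values`` is a float DataFrame indexed by sample id; ``tags`` maps every
    column to one of :data:`FEATURE_CLASSES`.
    """

    values: pd.DataFrame
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        untagged = set(self.values.columns) - set(self.tags)
        if untagged:
            raise ValidationError(f"untagged features: {sorted(untagged)}")
        bad = {t for t in self.tags.values()} - set(FEATURE_CLASSES)
        if bad:
            raise ValidationError(f"unknown feature classes: {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValidationError("feature matrix contains missing values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, classes) -> "FeatureMatrix":
        """Restrict to the feature columns whose tag is in ``classes``."""
        classes = {classes} if isinstance(classes, str) else set(classes)
        cols = [c for c in self.values.columns if self.tags[c] in classes]
        return FeatureMatrix(self.values[cols].copy(), {c: self.tags[c] for c in cols})

    def select(self, columns) -> "FeatureMatrix":
        """Restrict to explicitly named columns (order preserved)."""
        return FeatureMatrix(self.values[list(columns)].copy(),
                             {c: self.tags[c] for c in columns})


def _overlaps(variant: VariantRecord, chrom: str, start: int, end: int) -> bool:
    if variant.vclass == "CNA":
        return variant.chrom == chrom and variant.pos <= end and variant.cna_end >= start
    if variant.vclass == "SV":
        if variant.chrom == chrom and start <= variant.pos <= end:
            return True
        if variant.sv_mate is not None:
            mchrom, mpos = variant.sv_mate
            return mchrom == chrom and start <= mpos <= end
        return False
    return variant.chrom == chrom and start <= variant.pos <= end


def driver_features(
    variants_by_sample: dict[str, list[VariantRecord]],
    catalog: DriverCatalog,
    edge_years: float = 10.0,
    contigs: set[str] | None = None,
) -> pd.DataFrame:
    """Per-driver somatic mutation rates.

    A driver's feature is the number of somatic events of any class (SNV,
    indel, CNA, SV) overlapping its interval(s), divided by ``edge_years``.
    CNAs count when their span intersects the interval; SVs when either
    breakpoint falls inside.  When ``contigs`` (the genome's contig names) is
    given, a catalog interval on an unknown contig is a hard error.
    """
    if contigs is not None:
        unknown = catalog.contigs - set(contigs)
        if unknown:
            raise ValidationError(f"driver catalog references unknown contigs {sorted(unknown)}")
    rows = {}
    names = sorted(catalog.intervals)
    for sample, variants in variants_by_sample.items():
        row = {}
        for name in names:
            hits = sum(
                1
                for v in variants
                if any(_overlaps(v, chrom, s, e) for chrom, s, e in catalog.intervals[name])
            )
            row[f"driver_{name}"] = hits / edge_years
        rows[sample] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    return df[[f"driver_{n}" for n in names]]


def encode_clinical(table: ClinicalTable) -> pd.DataFrame:
    """Encode clinical attributes into numeric columns.

    binary -> one {0,1} column; categorical with k levels -> k indicator
    columns named ``attr|level`` (no reference level dropped; downstream
    collinearity pruning handles the redundancy); continuous -> passthrough.
    Missing values are imputed with the observed mode (binary/categorical)
    or median (continuous); per-attribute missingness is logged.
    """
    pieces = []
    for attr in table.data.columns:
        kind = table.kinds[attr]
        col = table.data[attr]
        n_missing = int(col.isna().sum())
        if n_missing:
            log.info("clinical attribute %r: imputing %d missing values", attr, n_missing)
        if kind == "continuous":
            col = pd.to_numeric(col, errors="coerce")
            col = col.fillna(col.median())
            pieces.append(col.rename(attr).astype(float))
        elif kind == "binary":
            filled = col.fillna(col.mode().iloc[0]) if n_missing else col
            levels = sorted(filled.astype(str).unique())
            if len(levels) > 2:
                raise ValidationError(f"binary attribute {attr!r} has levels {levels}")
            # map the lexicographically larger level to 1 for determinism
            mapping = {levels[0]: 0.0, levels[-1]: 1.0}
            pieces.append(filled.astype(str).map(mapping).rename(attr))
        elif kind == "categorical":
            filled = col.fillna(col.mode().iloc[0]) if n_missing else col
            filled = filled.astype(str)
            for level in sorted(filled.unique()):
                pieces.append((filled == level).astype(float).rename(f"{attr}|{level}"))
        else:  # pragma: no cover - guarded by ClinicalTable
            raise ValidationError(f"unknown kind {kind!r}")
    out = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=table.data.index)
    out.index.name = "sample"
    return out


def assemble_matrix(
    evo: pd.DataFrame,
    driver: pd.DataFrame,
    clinical: pd.DataFrame,
    outcomes: list[SurvivalRecord],
) -> tuple[FeatureMatrix, list[SurvivalRecord]]:
    """Inner-join feature sources and outcomes on sample id.

    Returns the aligned :class:`FeatureMatrix` (tagged per source) and the
    outcomes restricted to the joined cohort, in matrix row order.
    """
    sources = {"evolutionary": evo, "driver": driver, "clinical": clinical}
    outcome_samples = {r.sample for r in outcomes}
    common = set(outcome_samples)
    for df in sources.values():
        common &= set(df.index)
    if not common:
        raise ValidationError("no samples shared by all feature sources and outcomes")
    dropped = (set().union(*(set(df.index) for df in sources.values())) | outcome_samples) - common
    if dropped:
        log.info("assemble_matrix: dropped %d unmatched samples", len(dropped))
    order = sorted(common)
    tags: dict[str, str] = {}
    parts = []
    for tag, df in sources.items():
        for col in df.columns:
            if col in tags:
                raise ValidationError(f"duplicate feature name {col!r} across sources")
            tags[col] = tag
        parts.append(df.loc[order])
    values = pd.concat(parts, axis=1).astype(float)
    by_sample = {r.sample: r for r in outcomes}
    aligned = [by_sample[s] for s in order]
    return FeatureMatrix(values, tags), aligned
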