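"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates are 1-based inclusive (VCF convention).  CNAs are encoded
with symbolic ``<DUP>``/``<DEL>`` ALT alleles plus the standard ``END`` key;
SVs are breakend records whose mate locus is parsed from the BND ALT string,
or symbolic ``<INV>``/``<TRA>`` records.  Clone trees use a small documented
JSON schema (see :func:`write_clone_tree`) because per-edge multi-class
mutation counts and per-clone prevalences do not fit Newick cleanly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import pandas as pd
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
VARIANT_CLASSES = ("SNV", "INDEL", "CNA", "SV")
MUTATION_CLASS_KEYS = ("snv", "indel", "cna", "sv")
ENDPOINTS = ("OS", "DFS")
CLINICAL_KINDS = ("binary", "categorical", "continuous")

_BND_RE = re.compile(r"[\[\]]([^:\[\]]+):(\d+)[\[\]]")


class FormatError(ValueError):
    """A file could not be parsed as the declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class ContextUnavailableError(ValueError):
    """Trinucleotide context cannot be extracted (contig edge)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """One somatic event (SNV, indel, CNA or SV).

    ``pos`` is 1-based; for CNAs ``cna_end`` is the 1-based inclusive end so
    the affected length is ``cna_end - pos + 1``.  ``sv_mate`` holds the
    breakpoint partner locus ``(chrom, pos)`` for breakend SVs.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    vaf: float | None = None
    cna_end: int | None = None
    cna_dir: str | None = None
    sv_mate: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if self.vclass not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant class {self.vclass!r}")
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"VAF {self.vaf} outside [0, 1]")
        if self.vclass == "SNV":
            if (
                len(self.ref) != 1
                or len(self.alt) != 1
                or self.ref not in VALID_BASES
                or self.alt not in VALID_BASES
            ):
                raise ValidationError(
                    f"SNV alleles must be single ACGT bases, got {self.ref}>{self.alt}"
                )
            if self.ref == self.alt:
                raise ValidationError(f"SNV ref equals alt ({self.ref})")
        if self.vclass == "CNA":
            if self.cna_end is None or self.cna_end < self.pos:
                raise ValidationError(
                    f"CNA needs cna_end >= pos, got end={self.cna_end} pos={self.pos}"
                )
            if self.cna_dir not in ("amp", "del"):
                raise ValidationError(f"CNA direction must be amp/del, got {self.cna_dir!r}")

    @property
    def length(self) -> int:
        """Affected span in nucleotides (CNA only)."""
        if self.vclass != "CNA":
            raise ValueError("length is defined for CNA records only")
        return self.cna_end - self.pos + 1


@dataclass
class ReferenceGenome:
    """Uppercase nucleotide sequences keyed by contig name."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        allowed = VALID_BASES | {"N"}
        for name, seq in self.contigs.items():
            if set(seq) - allowed:
                bad = sorted(set(seq) - allowed)
                raise ValidationError(f"contig {name!r} contains non-ACGTN symbols {bad}")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise FormatError(f"duplicate contig {rec.id!r} in {path}")
            contigs[rec.id] = str(rec.seq).upper()
        if not contigs:
            raise FormatError(f"no FASTA records found in {path}")
        return cls(contigs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs


def fetch_context(genome: ReferenceGenome, chrom: str, pos: int) -> str:
    """Return the 3-mer centered at 1-based ``pos``.

    Raises :class:`ContextUnavailableError` when ``pos`` touches a contig
    edge; such variants are excluded from trinucleotide features but still
    counted in the total SNV rate.
    """
    if chrom not in genome.contigs:
        raise ValidationError(f"unknown contig {chrom!r}")
    seq = genome.contigs[chrom]
    if pos < 2 or pos > len(seq) - 1:
        raise ContextUnavailableError(f"position {chrom}:{pos} has no flanking bases")
    return seq[pos - 2 : pos + 1]


@dataclass
class CloneTree:
    """Rooted clonal lineage tree with per-edge mutation counts.

    Edges are keyed by their child clone.  ``edge_counts[child][k]`` is the
    number of class-``k`` mutations acquired on the edge parent->child, with
    ``k`` in :data:`MUTATION_CLASS_KEYS`.  ``prevalence`` maps non-root
    clones to cell fractions.
    """

    root: str
    parent_of: dict[str, str] = field(default_factory=dict)
    edge_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    prevalence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def nodes(self) -> list[str]:
        return [self.root] + sorted(self.parent_of)

    @property
    def clones(self) -> list[str]:
        """Non-root nodes, i.e. tumor clones."""
        return sorted(self.parent_of)

    def children_of(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parent_of.items() if p == node)

    def validate(self) -> None:
        if self.root in self.parent_of:
            raise ValidationError("root must not have a parent")
        nodes = set(self.parent_of) | {self.root}
        for child, parent in self.parent_of.items():
            if child == parent:
                raise ValidationError(f"node {child!r} is its own parent")
            if parent not in nodes:
                raise ValidationError(f"parent {parent!r} of {child!r} is not a node")
        # walk each node to the root; a cycle or a second root shows up as
        # a walk that never terminates or exceeds the node count
        for node in self.parent_of:
            seen = {node}
            cur = node
            while cur != self.root:
                cur = self.parent_of.get(cur)
                if cur is None or cur in seen:
                    raise ValidationError(f"node {node!r} does not reach the root (cycle?)")
                seen.add(cur)
        if set(self.edge_counts) != set(self.parent_of):
            raise ValidationError("edge_counts must be keyed by exactly the non-root nodes")
        for child, counts in self.edge_counts.items():
            for key in MUTATION_CLASS_KEYS:
                if counts.get(key, 0) < 0:
                    raise ValidationError(f"negative {key} count on edge to {child!r}")
        total = sum(self.prevalence.values())
        if total > 1.0 + 1e-6:
            raise ValidationError(f"clone prevalences sum to {total:.6f} > 1")
        for p in self.prevalence.values():
            if p < 0:
                raise ValidationError("negative clone prevalence")

    def edge_total(self, child: str) -> int:
        """Total mutation count on the edge above ``child`` (all classes)."""
        c = self.edge_counts[child]
        return sum(int(c.get(k, 0)) for k in MUTATION_CLASS_KEYS)


@dataclass
class SurvivalRecord:
    """Censored outcome: follow-up time ``y`` = min(T, C) and event flag."""

    sample: str
    endpoint: str
    y: float
    delta: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}")
        if not self.y > 0:
            raise ValidationError(f"follow-up time must be positive, got {self.y}")
        if self.delta not in (0, 1):
            raise ValidationError(f"event indicator must be 0 or 1, got {self.delta}")


@dataclass
class ClinicalTable:
    """Per-sample clinical attributes with declared kinds.

    ``data`` is indexed by sample id; ``kinds`` maps every column to one of
    ``binary``, ``categorical`` or ``continuous``.
    """

    data: pd.DataFrame
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.kinds)
        if missing:
            raise ValidationError(f"no kind declared for attributes {sorted(missing)}")
        for attr, kind in self.kinds.items():
            if kind not in CLINICAL_KINDS:
                raise ValidationError(f"unknown kind {kind!r} for attribute {attr!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = (
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
    '##FORMAT=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=TRA,Description="Translocation">',
)


def write_vcf(path, records: list[VariantRecord], contigs: dict[str, int] | None = None) -> None:
    """Write records as an uncompressed VCF 4.2 file.

    ``contigs`` maps contig name to length for the header; when omitted it is
    inferred from the records (length = max coordinate seen).
    """
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    if contigs is None:
        contigs = {}
        for r in records:
            end = max(r.pos, r.cna_end or 0, (r.sv_mate[1] if r.sv_mate else 0))
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), end + 1)
            if r.sv_mate:
                contigs[r.sv_mate[0]] = max(contigs.get(r.sv_mate[0], 0), r.sv_mate[1] + 1)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            if r.vclass == "CNA":
                alt = "<DUP>" if r.cna_dir == "amp" else "<DEL>"
                rec = out.new_record(
                    contig=r.chrom, start=r.pos - 1, alleles=(r.ref or "N", alt), stop=r.cna_end
                )
                rec.info["SVTYPE"] = "DUP" if r.cna_dir == "amp" else "DEL"
            elif r.vclass == "SV":
                if r.sv_mate is not None:
                    alt = f"{r.ref}[{r.sv_mate[0]}:{r.sv_mate[1]}["
                    rec = out.new_record(contig=r.chrom, start=r.pos - 1, alleles=(r.ref, alt))
                    rec.info["SVTYPE"] = "BND"
                else:
                    rec = out.new_record(contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt))
                    rec.info["SVTYPE"] = r.alt.strip("<>")
            else:
                rec = out.new_record(contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt))
            if r.vaf is not None:
                rec.info["VAF"] = r.vaf
            out.write(rec)


def _classify_vcf_record(rec) -> VariantRecord:
    alt = rec.alts[0] if rec.alts else "."
    vaf = None
    if "VAF" in rec.info:
        vaf = round(float(rec.info["VAF"]), 6)
    else:
        for sample in rec.samples.values():
            v = sample.get("VAF")
            if v is not None:
                vaf = round(float(v), 6)
                break
    pos = rec.pos  # pysam exposes the 1-based POS
    svtype = rec.info.get("SVTYPE")
    if alt in ("<DUP>", "<DEL>"):
        return VariantRecord(
            chrom=rec.contig,
            pos=pos,
            ref=rec.ref or "N",
            alt=alt,
            vclass="CNA",
            vaf=vaf,
            cna_end=rec.stop,
            cna_dir="amp" if alt == "<DUP>" else "del",
        )
    m = _BND_RE.search(alt)
    if m or svtype == "BND":
        mate = (m.group(1), int(m.group(2))) if m else None
        return VariantRecord(
            chrom=rec.contig, pos=pos, ref=rec.ref, alt=alt, vclass="SV", vaf=vaf, sv_mate=mate
        )
    if alt in ("<INV>", "<TRA>"):
        return VariantRecord(chrom=rec.contig, pos=pos, ref=rec.ref, alt=alt, vclass="SV", vaf=vaf)
    if len(rec.ref) == 1 and len(alt) == 1:
        return VariantRecord(chrom=rec.contig, pos=pos, ref=rec.ref, alt=alt, vclass="SNV", vaf=vaf)
    return VariantRecord(chrom=rec.contig, pos=pos, ref=rec.ref, alt=alt, vclass="INDEL", vaf=vaf)


def read_vcf(path, sample: str | None = None, reference: ReferenceGenome | None = None) -> list[VariantRecord]:
    """Read a VCF 4.x file into validated :class:`VariantRecord` objects.

    When ``reference`` is given, a record on a contig absent from the
    reference is a hard error (silent skipping would deflate features).
    """
    records: list[VariantRecord] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
    with vf:
        n_header = str(vf.header).count("\n")
        i = 0
        it = iter(vf)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as exc:  # htslib parse failure
                raise FormatError(f"{path}: malformed record near line {n_header + i + 1}: {exc}") from exc
            i += 1
            try:
                vrec = _classify_vcf_record(rec)
            except ValidationError as exc:
                raise ValidationError(f"{path} line {n_header + i}: {exc}") from exc
            if reference is not None and vrec.chrom not in reference:
                raise ValidationError(
                    f"{path} line {n_header + i}: contig {vrec.chrom!r} not in reference"
                )
            records.append(vrec)
    return records


# ---------------------------------------------------------------------------
# Clone tree JSON
# ---------------------------------------------------------------------------


def write_clone_tree(path, tree: CloneTree, sample: str | None = None) -> None:
    """Serialize one clone tree to JSON.

    Schema::

        {"sample": "S1",
         "root": "root",
         "parents": {"c1": "root", "c2": "c1"},
         "edge_counts": {"c1": {"snv": 30, "indel": 0, "cna": 1, "sv": 0}, ...},
         "prevalence": {"c1": 0.6, "c2": 0.2}}
    """
    payload = {
        "sample": sample,
        "root": tree.root,
        "parents": tree.parent_of,
        "edge_counts": {
            c: {k: int(v.get(k, 0)) for k in MUTATION_CLASS_KEYS}
            for c, v in tree.edge_counts.items()
        },
        "prevalence": tree.prevalence,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_clone_tree(path) -> CloneTree:
    """Read a clone tree JSON file (see :func:`write_clone_tree`)."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("root", "parents", "edge_counts"):
        if key not in payload:
            raise FormatError(f"{path}: missing required key {key!r}")
    return CloneTree(
        root=payload["root"],
        parent_of=dict(payload["parents"]),
        edge_counts={c: dict(v) for c, v in payload["edge_counts"].items()},
        prevalence=dict(payload.get("prevalence", {})),
    )


# ---------------------------------------------------------------------------
# Clinical and outcome TSVs
# ---------------------------------------------------------------------------


def read_outcomes(path, endpoint: str) -> list[SurvivalRecord]:
    """Read censored outcomes from a header-ed TSV.

    Accepts either endpoint-specific columns (``os_time``/``os_event`` or
    ``dfs_time``/``dfs_event``) or generic ``time``/``event`` columns.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise FormatError(f"{path}: missing 'sample' column")
    lo = endpoint.lower()
    if f"{lo}_time" in df.columns:
        tcol, ecol = f"{lo}_time", f"{lo}_event"
    elif "time" in df.columns:
        tcol, ecol = "time", "event"
    else:
        raise FormatError(f"{path}: no time column for endpoint {endpoint}")
    if ecol not in df.columns:
        raise FormatError(f"{path}: missing event column {ecol!r}")
    records = []
    for _, row in df.iterrows():
        ev = row[ecol]
        if float(ev) not in (0.0, 1.0):
            raise ValidationError(f"{path}: event value {ev!r} for {row['sample']} not in {{0,1}}")
        records.append(
            SurvivalRecord(sample=row["sample"], endpoint=endpoint, y=float(row[tcol]), delta=int(ev))
        )
    return records


def write_outcomes(path, records_by_endpoint: dict[str, list[SurvivalRecord]]) -> None:
    """Write outcomes for one or more endpoints into a single TSV."""
    frames = []
    for endpoint, records in records_by_endpoint.items():
        lo = endpoint.lower()
        frames.append(
            pd.DataFrame(
                {f"{lo}_time": [r.y for r in records], f"{lo}_event": [r.delta for r in records]},
                index=[r.sample for r in records],
            )
        )
    out = pd.concat(frames, axis=1)
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV whose second line declares per-column kinds.

    Format::

        sample  age     stage   tumor_free
        #kind   continuous      categorical     binary
        S1      61.0    ii      1
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        kind_line = fh.readline().rstrip("\n").split("\t")
    if not kind_line or kind_line[0] != "#kind":
        raise FormatError(f"{path}: second line must start with '#kind'")
    if len(kind_line) != len(header):
        raise FormatError(f"{path}: kind line has {len(kind_line)} fields, header {len(header)}")
    kinds = dict(zip(header[1:], kind_line[1:]))
    df = pd.read_csv(path, sep="\t", skiprows=[1], dtype={header[0]: str})
    df = df.set_index(header[0])
    df.index.name = "sample"
    return ClinicalTable(data=df, kinds=kinds)


def write_clinical(path, table: ClinicalTable) -> None:
    cols = list(table.data.columns)
    with open(path, "w") as fh:
        fh.write("\t".join(["sample"] + cols) + "\n")
        fh.write("\t".join(["#kind"] + [table.kinds[c] for c in cols]) + "\n")
        for sample, row in table.data.iterrows():
            fields = [str(sample)] + ["" if pd.isna(v) else str(v) for v in row]
            fh.write("\t".join(fields) + "\n")


def joined_samples(*sample_sets: list[str]) -> list[str]:
    """Sorted intersection of sample id collections; drops are logged."""
    sets = [set(s) for s in sample_sets]
    common = set.intersection(*sets) if sets else set()
    dropped = set.union(*sets) - common if sets else set()
    if dropped:
        log.info("dropping %d samples absent from at least one input", len(dropped))
    return sorted(common)
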