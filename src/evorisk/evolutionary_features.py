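"""Evolutionary feature vectors: strand-collapsed substitution rates, the 96
trinucleotide-context rates, CNA/SV rate classes and clonal-tree statistics.

The cumulative ("two-node tree") features treat all of a sample's somatic
variants as acquired along a single normal-to-tumor edge of fixed duration
(``edge_years``, 10 by default), so each feature is a per-year count.  The
scale is arbitrary and cancels in downstream model fitting.
"""

from __future__ import annotations

from collections import Counter

from .genomic_io import (
    CloneTree,
    ContextUnavailableError,
    ReferenceGenome,
    ValidationError,
    VariantRecord,
    fetch_context,
)

PYRIMIDINES = ("C", "T")
PURINES = ("A", "G")
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 6 pyrimidine-centered substitution classes
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: threshold separating "large" from "small" CNAs; strictly-greater is large
CNA_SIZE_THRESHOLD_NT = 500_000

CUMULATIVE_FEATURES = (
    "snv_rate",
    *(f"{c}_rate" for c in SUBSTITUTION_CLASSES),
    "indel_rate",
    "cna_rate",
    "cna_amp_rate",
    "cna_del_rate",
    "cna_lg_rate",
    "cna_sm_rate",
    "sv_rate",
)
PHYLO_FEATURES = ("num_clone", "height", "branch_mean", "branch_mean_sv")


class AmbiguousContextError(ValueError):
    """Trinucleotide context contains an N; excluded from the 96 classes."""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_substitution(ref: str, alt: str) -> str:
    """Map a single-base substitution to its pyrimidine-centered class.

    Purine-centered substitutions are complemented (G>T becomes C>A, A>G
    becomes T>C); pyrimidine-centered ones are returned unchanged.  There are
    exactly ``4 * 3 / 2 = 6`` resulting classes.
    """
    if ref not in BASES or alt not in BASES:
        raise ValidationError(f"substitution bases must be ACGT, got {ref}>{alt}")
    if ref == alt:
        raise ValidationError(f"ref equals alt ({ref})")
    if ref in PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def trinucleotide_class(context: str, ref: str, alt: str) -> str:
    """Classify an SNV into one of the 96 ``N_l[N_x>N_y]N_r`` classes.

    ``context`` is the reference 3-mer centered on the variant; its center
    must equal ``ref``.  When the center is a purine the whole trinucleotide
    is reverse-complemented before classification, so the result is always
    pyrimidine-centered.  A context containing N raises
    :class:`AmbiguousContextError` (the variant stays in the total SNV rate
    but is excluded from the 96 counts).
    """
    if len(context) != 3:
        raise ValidationError(f"context must be a 3-mer, got {context!r}")
    if "N" in context:
        raise AmbiguousContextError(f"ambiguous context {context!r}")
    if context[1] != ref:
        raise ValidationError(f"context center {context[1]!r} does not match ref {ref!r}")
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValidationError(f"invalid substitution {ref}>{alt}")
    if ref in PURINES:
        context = reverse_complement(context)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def enumerate_substitution_classes() -> list[str]:
    """All distinct collapsed classes over the 12 ordered base substitutions."""
    classes = {
        collapse_substitution(r, a) for r in BASES for a in BASES if r != a
    }
    return sorted(classes)


def enumerate_trinucleotide_classes() -> list[str]:
    """All distinct classes over 4x4 contexts crossed with 12 substitutions."""
    classes = set()
    for left in BASES:
        for right in BASES:
            for ref in BASES:
                for alt in BASES:
                    if ref == alt:
                        continue
                    classes.add(trinucleotide_class(f"{left}{ref}{right}", ref, alt))
    return sorted(classes)


TRINUCLEOTIDE_CLASSES = tuple(enumerate_trinucleotide_classes())


def cumulative_features(
    variants: list[VariantRecord],
    genome: ReferenceGenome,
    snp_mask: set[tuple[str, int]] | None = None,
    edge_years: float = 10.0,
) -> dict[str, float]:
    """Cumulative (two-node tree) evolutionary features for one sample.

    Returns a dict over :data:`CUMULATIVE_FEATURES` plus the 96 trinucleotide
    rates.  Positions in ``snp_mask`` (``(chrom, pos)`` pairs of common
    germline SNPs) are screened out first.  Every rate is a per-year count
    over the ``edge_years`` normal-to-tumor edge.  CNAs strictly longer than
    :data:`CNA_SIZE_THRESHOLD_NT` are "large".
    """
    if edge_years <= 0:
        raise ValueError("edge_years must be positive")
    if snp_mask:
        variants = [v for v in variants if (v.chrom, v.pos) not in snp_mask]
    counts: Counter[str] = Counter()
    for v in variants:
        if v.vclass == "SNV":
            counts["snv"] += 1
            try:
                ctx = fetch_context(genome, v.chrom, v.pos)
                counts[collapse_substitution(v.ref, v.alt)] += 1
                counts[trinucleotide_class(ctx, v.ref, v.alt)] += 1
            except (ContextUnavailableError, AmbiguousContextError):
                # still collapse without context when only the context is bad
                if v.ref in BASES and v.alt in BASES:
                    counts[collapse_substitution(v.ref, v.alt)] += 1
        elif v.vclass == "INDEL":
            counts["indel"] += 1
        elif v.vclass == "CNA":
            counts["cna"] += 1
            counts["cna_amp" if v.cna_dir == "amp" else "cna_del"] += 1
            counts["cna_lg" if v.length > CNA_SIZE_THRESHOLD_NT else "cna_sm"] += 1
        elif v.vclass == "SV":
            counts["sv"] += 1
    feats = {
        "snv_rate": counts["snv"] / edge_years,
        "indel_rate": counts["indel"] / edge_years,
        "cna_rate": counts["cna"] / edge_years,
        "cna_amp_rate": counts["cna_amp"] / edge_years,
        "cna_del_rate": counts["cna_del"] / edge_years,
        "cna_lg_rate": counts["cna_lg"] / edge_years,
        "cna_sm_rate": counts["cna_sm"] / edge_years,
        "sv_rate": counts["sv"] / edge_years,
    }
    for c in SUBSTITUTION_CLASSES:
        feats[f"{c}_rate"] = counts[c] / edge_years
    for c in TRINUCLEOTIDE_CLASSES:
        feats[c] = counts[c] / edge_years
    return feats


def phylo_features(tree: CloneTree) -> dict[str, float]:
    """Clonal-tree statistics: clone number, height, mean branch lengths.

    Edge length is the total mutation count on the edge (all classes);
    ``branch_mean_sv`` averages SV counts only.  ``num_clone`` counts tumor
    clones, i.e. non-root nodes.  A root-only tree yields all zeros.
    """
    clones = tree.clones
    if not clones:
        return {"num_clone": 0.0, "height": 0.0, "branch_mean": 0.0, "branch_mean_sv": 0.0}
    totals = {c: tree.edge_total(c) for c in clones}
    depth: dict[str, float] = {tree.root: 0.0}

    def _depth(node: str) -> float:
        if node not in depth:
            depth[node] = _depth(tree.parent_of[node]) + totals[node]
        return depth[node]

    height = max(_depth(c) for c in clones)
    branch_mean = sum(totals.values()) / len(clones)
    branch_mean_sv = sum(int(tree.edge_counts[c].get("sv", 0)) for c in clones) / len(clones)
    return {
        "num_clone": float(len(clones)),
        "height": float(height),
        "branch_mean": float(branch_mean),
        "branch_mean_sv": float(branch_mean_sv),
    }


def sample_features(
    variants: list[VariantRecord],
    tree: CloneTree | None,
    genome: ReferenceGenome,
    snp_mask: set[tuple[str, int]] | None = None,
    edge_years: float = 10.0,
) -> dict[str, float]:
    """Full evolutionary feature vector (cumulative + phylogenetic) for one sample."""
    feats = cumulative_features(variants, genome, snp_mask=snp_mask, edge_years=edge_years)
    if tree is not None:
        feats.update(phylo_features(tree))
    return feats
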