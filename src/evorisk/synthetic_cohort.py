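"""Synthetic cohort generator.

Produces cohorts with the statistical structure the analysis assumes:
per-tumor mutational-phenotype parameters (signature mixture, SNV/indel/
CNA/SV rates), variant lists and clone trees realized from them, driver and
clinical covariates with configurable hazard links, and censored survival
times drawn from a proportional-hazards model with known coefficients.
Everything is a pure function of ``(config, seed)``.

Hazard model: the per-sample log-hazard is ``eta = sum_k beta_true[k] *
covariate_k`` over generative covariates.  Latent phenotype strengths
``z_snv``, ``z_indel``, ``z_cna``, ``z_sv`` are standard normal and scale
the per-class rates multiplicatively (``rate = base * exp(sigma * z)``),
so hazard links to phenotype act through the ``z_*`` keys.  Clinical
covariates enter by name (categorical levels as ``name|level``), and driver
mutation indicators by driver name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .annotation_features import DriverCatalog
from .evolutionary_features import (
    COMPLEMENT,
    PYRIMIDINES,
    TRINUCLEOTIDE_CLASSES,
)
from .genomic_io import (
    ClinicalTable,
    CloneTree,
    ReferenceGenome,
    SurvivalRecord,
    VariantRecord,
)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class RatePriors:
    """Cohort-level base rates (events per year) and per-sample log-normal spread."""

    snv_rate: float = 3.0
    snv_sigma: float = 0.5
    indel_rate: float = 0.4
    indel_sigma: float = 0.3
    cna_rate: float = 0.5
    cna_sigma: float = 0.5
    sv_rate: float = 0.3
    sv_sigma: float = 0.5
    cna_amp_frac: float = 0.5
    cna_lg_frac: float = 0.5

    def __post_init__(self) -> None:
        for name in ("snv_rate", "indel_rate", "cna_rate", "sv_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("cna_amp_frac", "cna_lg_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")


@dataclass
class DriverSpec:
    """A driver interval, its mutation probability and phenotype couplings.

    ``rate_multipliers`` (e.g. ``{"snv": 2.0}``) scale the carrier's
    per-class rates, reproducing driver-phenotype correlation without
    modeling mechanism.
    """

    name: str
    chrom: str
    start: int
    end: int
    mut_prob: float = 0.1
    rate_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ConfigError(f"driver {self.name!r}: bad interval")
        if not 0 <= self.mut_prob <= 1:
            raise ConfigError(f"driver {self.name!r}: mut_prob outside [0, 1]")


@dataclass
class ClinicalVarSpec:
    """One clinical attribute: kind, generating distribution."""

    name: str
    kind: str = "binary"  # binary | categorical | continuous
    p: float = 0.5  # binary success probability
    levels: tuple = ("a", "b", "c")  # categorical
    probs: tuple | None = None
    mean: float = 0.0  # continuous
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ConfigError(f"clinical {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class SimulationConfig:
    n_samples: int = 100
    contigs: dict = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    signature_weights: np.ndarray | None = None  # length 96 over TRINUCLEOTIDE_CLASSES
    signature_concentration: float | None = None  # Dirichlet conc.; None = shared mixture
    rates: RatePriors = field(default_factory=RatePriors)
    drivers: list = field(default_factory=list)
    clinical: list = field(default_factory=list)
    beta_true: dict = field(default_factory=dict)
    edge_years: float = 10.0
    baseline: tuple = ("exponential", 0.02)
    censoring: tuple | None = ("exponential", 0.02)
    clone_range: tuple = (1, 5)
    branched_prob: float = 0.5
    missing_context: str = "error"  # or "resample"
    seed: int = 0
    genome_seed: int | None = None  # defaults to ``seed``; fix it to share one reference

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if not self.contigs or any(l <= 0 for l in self.contigs.values()):
            raise ConfigError("contigs must be non-empty with positive lengths")
        if max(self.contigs.values()) < 3 and self.rates.snv_rate > 0:
            raise ConfigError("genome too short to place SNVs with context")
        if self.signature_weights is not None:
            w = np.asarray(self.signature_weights, dtype=float)
            if w.shape != (96,) or (w < 0).any() or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
                raise ConfigError("signature_weights must be 96 nonnegative values summing to 1")
        if self.missing_context not in ("error", "resample"):
            raise ConfigError("missing_context must be 'error' or 'resample'")
        if self.edge_years <= 0:
            raise ConfigError("edge_years must be positive")

    def driver_catalog(self) -> DriverCatalog:
        return DriverCatalog({d.name: [(d.chrom, d.start, d.end)] for d in self.drivers})


@dataclass
class GroundTruth:
    """Everything needed to check recovery: generative covariates, the true
    hazard coefficients and linear predictor, and uncensored event times."""

    beta_true: dict
    covariates: pd.DataFrame
    eta: pd.Series
    rates: pd.DataFrame
    event_times: dict  # endpoint -> np.ndarray of T before censoring

    def to_dict(self) -> dict:
        return {
            "beta_true": self.beta_true,
            "covariates": self.covariates.to_dict(orient="index"),
            "eta": self.eta.to_dict(),
            "rates": self.rates.to_dict(orient="index"),
            "event_times": {k: list(map(float, v)) for k, v in self.event_times.items()},
        }


@dataclass
class SimulatedCohort:
    genome: ReferenceGenome
    variants: dict  # sample -> list[VariantRecord]
    trees: dict  # sample -> CloneTree
    clinical: ClinicalTable
    outcomes: dict  # endpoint -> list[SurvivalRecord]
    ground_truth: GroundTruth

    @property
    def samples(self) -> list[str]:
        return list(self.variants)


def _rng(*key) -> np.random.Generator:
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in key])


# ---------------------------------------------------------------------------
# Genome and trinucleotide-context index
# ---------------------------------------------------------------------------


def make_genome(contigs: dict, seed: int) -> ReferenceGenome:
    """Random toy reference with the given contig lengths (seeded)."""
    rng = _rng(seed, 7)
    ascii_map = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    seqs = {}
    for name, length in contigs.items():
        codes = rng.integers(0, 4, size=int(length))
        seqs[name] = ascii_map[codes].tobytes().decode()
    return ReferenceGenome(seqs)


class ContextIndex:
    """Positions of every pyrimidine-collapsed trinucleotide context.

    For each of the 32 contexts stores the (contig, 1-based position) pairs
    whose reference 3-mer matches it after strand collapsing.  Lets the
    simulator place an SNV of a requested trinucleotide class at a position
    whose context genuinely matches.
    """

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.contig_names = list(genome.contigs)
        by_ctx: dict[int, list] = {}
        for ci, name in enumerate(self.contig_names):
            seq = genome.contigs[name]
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            lut = np.full(256, 4, dtype=np.int8)
            for b, i in _CODE.items():
                lut[ord(b)] = i
            codes = lut[codes]
            left, center, right = codes[:-2], codes[1:-1], codes[2:]
            valid = (left < 4) & (center < 4) & (right < 4)
            pyr = (center == 1) | (center == 3)  # C or T
            l = np.where(pyr, left, 3 - right)
            c2 = np.where(pyr, (center == 3).astype(int), (center == 0).astype(int))
            r = np.where(pyr, right, 3 - left)
            ctx = l * 8 + c2 * 4 + r
            pos = np.arange(2, len(codes))  # 1-based center positions
            for cid in range(32):
                sel = valid & (ctx == cid)
                if sel.any():
                    by_ctx.setdefault(cid, []).append((ci, pos[sel]))
        self._index = {}
        for cid, chunks in by_ctx.items():
            contig_idx = np.concatenate([np.full(len(p), ci) for ci, p in chunks])
            positions = np.concatenate([p for _, p in chunks])
            self._index[cid] = (contig_idx, positions)

    @staticmethod
    def context_id(left: str, center: str, right: str) -> int:
        if center not in PYRIMIDINES:
            left, center, right = COMPLEMENT[right], COMPLEMENT[center], COMPLEMENT[left]
        return _CODE[left] * 8 + (1 if center == "T" else 0) * 4 + _CODE[right]

    def has_context(self, cid: int) -> bool:
        return cid in self._index

    def sample_positions(self, cid: int, count: int, rng: np.random.Generator):
        contig_idx, positions = self._index[cid]
        replace = count > len(positions)
        take = rng.choice(len(positions), size=count, replace=replace)
        return [(self.contig_names[contig_idx[i]], int(positions[i])) for i in take]


@lru_cache(maxsize=4)
def _cached_genome_index(contig_items: tuple, seed: int):
    genome = make_genome(dict(contig_items), seed)
    return genome, ContextIndex(genome)


def uniform_signature() -> np.ndarray:
    return np.full(96, 1.0 / 96)


def point_mass_signature(tri_class: str) -> np.ndarray:
    w = np.zeros(96)
    w[TRINUCLEOTIDE_CLASSES.index(tri_class)] = 1.0
    return w


# ---------------------------------------------------------------------------
# Variant draws
# ---------------------------------------------------------------------------

_CLASS_CTX_ALT = []
for _cls in TRINUCLEOTIDE_CLASSES:  # "A[C>T]G"
    _left, _rest = _cls[0], _cls[2:]
    _ref, _alt, _right = _rest[0], _rest[2], _rest[4]
    _CLASS_CTX_ALT.append((ContextIndex.context_id(_left, _ref, _right), _ref, _alt))


def draw_snvs(
    n_snv: int,
    weights: np.ndarray,
    index: ContextIndex,
    rng: np.random.Generator,
    missing_context: str = "error",
) -> list[VariantRecord]:
    """Place ``n_snv`` SNVs whose trinucleotide classes follow ``weights``.

    Class counts are multinomial; each SNV lands on a genome position whose
    (strand-collapsed) context matches its class, with ref/alt complemented
    when the matched strand carries the purine.
    """
    weights = np.asarray(weights, dtype=float)
    if not math.isclose(weights.sum(), 1.0, rel_tol=1e-6):
        raise ConfigError("signature weights must sum to 1")
    available = np.array([index.has_context(cid) for cid, _, _ in _CLASS_CTX_ALT])
    if ((weights > 0) & ~available).any():
        if missing_context == "error":
            bad = [TRINUCLEOTIDE_CLASSES[i] for i in np.where((weights > 0) & ~available)[0]]
            raise ConfigError(f"no genome positions for requested classes {bad[:5]}")
        weights = np.where(available, weights, 0.0)
        weights = weights / weights.sum()
    counts = rng.multinomial(n_snv, weights)
    records: list[VariantRecord] = []
    for k, m in enumerate(counts):
        if m == 0:
            continue
        cid, ref, alt = _CLASS_CTX_ALT[k]
        for chrom, pos in index.sample_positions(cid, int(m), rng):
            center = index.genome.contigs[chrom][pos - 1]
            if center in PYRIMIDINES:
                r, a = ref, alt
            else:
                r, a = COMPLEMENT[ref], COMPLEMENT[alt]
            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=r, alt=a, vclass="SNV",
                    vaf=round(float(rng.uniform(0.05, 0.95)), 6),
                )
            )
    return records


def _weighted_contig(contigs: dict, rng, min_length: int = 1) -> tuple[str, int]:
    eligible = [(n, l) for n, l in contigs.items() if l >= min_length]
    if not eligible:
        raise ConfigError(f"no contig of length >= {min_length}")
    names, lengths = zip(*eligible)
    probs = np.asarray(lengths, dtype=float)
    probs /= probs.sum()
    i = rng.choice(len(names), p=probs)
    return names[i], lengths[i]


def draw_indels(n: int, genome: ReferenceGenome, rng) -> list[VariantRecord]:
    records = []
    lengths = {k: len(v) for k, v in genome.contigs.items()}
    for _ in range(n):
        chrom, length = _weighted_contig(lengths, rng, min_length=3)
        pos = int(rng.integers(2, length - 1))
        seq = genome.contigs[chrom]
        if rng.random() < 0.5:  # insertion
            ref = seq[pos - 1]
            alt = ref + _BASES[rng.integers(0, 4)]
        else:  # single-base deletion
            ref = seq[pos - 1 : pos + 1]
            alt = seq[pos - 1]
        if "N" in ref:
            continue
        records.append(
            VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, vclass="INDEL",
                          vaf=round(float(rng.uniform(0.05, 0.95)), 6))
        )
    return records


def draw_cnas(n: int, genome: ReferenceGenome, rng, amp_frac: float, lg_frac: float) -> list[VariantRecord]:
    from .evolutionary_features import CNA_SIZE_THRESHOLD_NT

    records = []
    lengths = {k: len(v) for k, v in genome.contigs.items()}
    for _ in range(n):
        large = rng.random() < lg_frac
        if large:
            max_len = max(lengths.values()) - 1
            if max_len <= CNA_SIZE_THRESHOLD_NT + 1:
                raise ConfigError("contigs too short for large CNAs")
            size = int(rng.integers(CNA_SIZE_THRESHOLD_NT + 1, min(max_len, 2 * CNA_SIZE_THRESHOLD_NT)))
        else:
            size = int(rng.integers(1_000, CNA_SIZE_THRESHOLD_NT + 1))
        chrom, length = _weighted_contig(lengths, rng, min_length=size + 1)
        pos = int(rng.integers(1, length - size + 1))
        amp = rng.random() < amp_frac
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref="N", alt="<DUP>" if amp else "<DEL>",
                vclass="CNA", cna_end=pos + size - 1, cna_dir="amp" if amp else "del",
                vaf=round(float(rng.uniform(0.05, 0.95)), 6),
            )
        )
    return records


def draw_svs(n: int, genome: ReferenceGenome, rng) -> list[VariantRecord]:
    records = []
    lengths = {k: len(v) for k, v in genome.contigs.items()}
    for _ in range(n):
        chrom, length = _weighted_contig(lengths, rng, min_length=4)
        pos = int(rng.integers(2, length))
        mchrom, mlength = _weighted_contig(lengths, rng, min_length=4)
        mpos = int(rng.integers(2, mlength))
        ref = genome.contigs[chrom][pos - 1]
        if ref == "N":
            ref = "A"
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=f"{ref}[{mchrom}:{mpos}[", vclass="SV",
                sv_mate=(mchrom, mpos), vaf=round(float(rng.uniform(0.05, 0.95)), 6),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Clone trees
# ---------------------------------------------------------------------------


def build_clone_tree(
    class_counts: dict,
    rng: np.random.Generator,
    n_clones: int | None = None,
    clone_range: tuple = (1, 5),
    branched_prob: float = 0.5,
) -> CloneTree:
    """Partition a sample's realized variant counts over a random clone tree.

    The clone count is uniform on ``clone_range`` (capped by the number of
    variants); topology is linear or branched per a Bernoulli draw.  Clone
    prevalences are descending shares of a Dirichlet draw assigned in
    creation (parent-before-child) order, so every child's prevalence is at
    most its parent's and the clone total stays below 1.
    """
    total = sum(int(v) for v in class_counts.values())
    if n_clones is not None:
        if n_clones > max(total, 1):
            raise ConfigError(f"{n_clones} clones requested but only {total} variants to distribute")
        c = n_clones
    else:
        hi = max(1, min(clone_range[1], total))
        lo = min(clone_range[0], hi)
        c = int(rng.integers(lo, hi + 1))
    names = [f"clone{i + 1}" for i in range(c)]
    branched = rng.random() < branched_prob
    parent_of = {}
    for i, name in enumerate(names):
        if i == 0:
            parent_of[name] = "root"
        elif branched:
            parent_of[name] = (["root"] + names[:i])[int(rng.integers(0, i + 1))]
        else:
            parent_of[name] = names[i - 1]
    edge_counts = {name: {"snv": 0, "indel": 0, "cna": 0, "sv": 0} for name in names}
    for key, count in class_counts.items():
        alloc = rng.multinomial(int(count), np.full(c, 1.0 / c))
        for name, a in zip(names, alloc):
            edge_counts[name][key] = int(a)
    w = np.sort(rng.dirichlet(np.ones(c + 1)))[::-1]
    prevalence = {name: float(w[i + 1]) for i, name in enumerate(names)}
    return CloneTree(root="root", parent_of=parent_of, edge_counts=edge_counts, prevalence=prevalence)


def partition_variants(variants: list[VariantRecord]) -> dict:
    counts = {"snv": 0, "indel": 0, "cna": 0, "sv": 0}
    for v in variants:
        counts[v.vclass.lower()] += 1
    return counts


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def draw_survival(eta, baseline, censoring, rng):
    """Event and censoring times under proportional hazards.

    The hazard of sample *i* is ``h0(t) * exp(eta_i)``; event times come
    from inverse-transform sampling (closed form for exponential and
    Weibull baselines).  Returns ``(y, delta, T)`` with ``y = min(T, C)``
    and ``delta = 1[T <= C]``; ``censoring=None`` means no censoring.
    """
    eta = np.asarray(eta, dtype=float)
    n = len(eta)
    E = rng.exponential(size=n)  # unit-rate exponentials
    kind = baseline[0]
    if kind == "exponential":
        rate = float(baseline[1])
        if rate <= 0:
            raise ConfigError("exponential baseline rate must be positive")
        T = E / (rate * np.exp(eta))
    elif kind == "weibull":
        shape, scale = float(baseline[1]), float(baseline[2])
        if shape <= 0 or scale <= 0:
            raise ConfigError("weibull baseline parameters must be positive")
        T = scale * (E / np.exp(eta)) ** (1.0 / shape)
    else:
        raise ConfigError(f"unknown baseline family {kind!r}")
    if censoring is None:
        C = np.full(n, np.inf)
    elif censoring[0] == "exponential":
        crate = float(censoring[1])
        if crate <= 0:
            raise ConfigError("censoring rate must be positive")
        C = rng.exponential(1.0 / crate, size=n)
    elif censoring[0] == "uniform":
        C = rng.uniform(float(censoring[1]), float(censoring[2]), size=n)
    else:
        raise ConfigError(f"unknown censoring family {censoring[0]!r}")
    y = np.minimum(T, C)
    delta = (T <= C).astype(int)
    return y, delta, T


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def _draw_clinical(spec: ClinicalVarSpec, n: int, rng):
    """Returns (raw column for the clinical table, dict of covariate columns)."""
    if spec.kind == "binary":
        x = (rng.random(n) < spec.p).astype(int)
        return x, {spec.name: x.astype(float)}
    if spec.kind == "continuous":
        x = rng.normal(spec.mean, spec.sd, size=n)
        return np.round(x, 6), {spec.name: x}
    probs = np.asarray(spec.probs, dtype=float) if spec.probs else np.full(len(spec.levels), 1.0 / len(spec.levels))
    idx = rng.choice(len(spec.levels), size=n, p=probs / probs.sum())
    raw = np.asarray([spec.levels[i] for i in idx], dtype=object)
    cols = {f"{spec.name}|{lvl}": (raw == lvl).astype(float) for lvl in spec.levels}
    return raw, cols


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full synthetic cohort (see module docstring).

    Deterministic in ``config.seed``: named RNG streams are derived per
    component and per sample, so identical configs give identical cohorts.
    """
    n = config.n_samples
    seed = config.seed
    samples = [f"S{i:04d}" for i in range(n)]
    gseed = config.genome_seed if config.genome_seed is not None else seed
    genome, index = _cached_genome_index(tuple(config.contigs.items()), gseed)

    z = _rng(seed, 11).standard_normal((n, 4))  # snv, indel, cna, sv
    covariates = pd.DataFrame(
        {"z_snv": z[:, 0], "z_indel": z[:, 1], "z_cna": z[:, 2], "z_sv": z[:, 3]}, index=samples
    )

    rng_clin = _rng(seed, 12)
    clin_raw = {}
    kinds = {}
    for spec in config.clinical:
        raw, cols = _draw_clinical(spec, n, rng_clin)
        clin_raw[spec.name] = raw
        kinds[spec.name] = spec.kind
        for cname, cvals in cols.items():
            covariates[cname] = cvals
    clinical = ClinicalTable(pd.DataFrame(clin_raw, index=pd.Index(samples, name="sample")), kinds)

    rng_drv = _rng(seed, 13)
    driver_mut = {}
    for d in config.drivers:
        driver_mut[d.name] = (rng_drv.random(n) < d.mut_prob).astype(int)
        covariates[d.name] = driver_mut[d.name].astype(float)

    r = config.rates
    multipliers = {k: np.ones(n) for k in ("snv", "indel", "cna", "sv")}
    for d in config.drivers:
        for key, mult in d.rate_multipliers.items():
            multipliers[key] = multipliers[key] * np.where(driver_mut[d.name] == 1, mult, 1.0)
    rates = pd.DataFrame(
        {
            "snv": r.snv_rate * np.exp(r.snv_sigma * z[:, 0]) * multipliers["snv"],
            "indel": r.indel_rate * np.exp(r.indel_sigma * z[:, 1]) * multipliers["indel"],
            "cna": r.cna_rate * np.exp(r.cna_sigma * z[:, 2]) * multipliers["cna"],
            "sv": r.sv_rate * np.exp(r.sv_sigma * z[:, 3]) * multipliers["sv"],
        },
        index=samples,
    )

    base_w = config.signature_weights if config.signature_weights is not None else uniform_signature()
    base_w = np.asarray(base_w, dtype=float)
    rng_sig = _rng(seed, 14)

    missing = set(config.beta_true) - set(covariates.columns)
    if missing:
        raise ConfigError(f"beta_true references unknown covariates {sorted(missing)}")
    eta = pd.Series(np.zeros(n), index=samples)
    for key, b in config.beta_true.items():
        eta = eta + float(b) * covariates[key].to_numpy()

    variants = {}
    trees = {}
    rate_arr = {k: rates[k].to_numpy() for k in ("snv", "indel", "cna", "sv")}
    for i, s in enumerate(samples):
        rng_v = _rng(seed, 15, i)
        if config.signature_concentration:
            pos_w = np.maximum(base_w, 1e-12)
            w = rng_sig.dirichlet(config.signature_concentration * pos_w / pos_w.sum())
        else:
            w = base_w
        n_snv = int(rng_v.poisson(rate_arr["snv"][i] * config.edge_years))
        n_indel = int(rng_v.poisson(rate_arr["indel"][i] * config.edge_years))
        n_cna = int(rng_v.poisson(rate_arr["cna"][i] * config.edge_years))
        n_sv = int(rng_v.poisson(rate_arr["sv"][i] * config.edge_years))
        recs = draw_snvs(n_snv, w, index, rng_v, config.missing_context)
        recs += draw_indels(n_indel, genome, rng_v)
        recs += draw_cnas(n_cna, genome, rng_v, r.cna_amp_frac, r.cna_lg_frac)
        recs += draw_svs(n_sv, genome, rng_v)
        for d in config.drivers:  # carriers get one SNV inside the driver interval
            if driver_mut[d.name][i]:
                lo = max(2, d.start)
                hi = min(d.end, len(genome.contigs[d.chrom]) - 1)
                pos = int(rng_v.integers(lo, hi + 1))
                ref = genome.contigs[d.chrom][pos - 1]
                alt = _BASES[(_CODE[ref] + int(rng_v.integers(1, 4))) % 4] if ref in _CODE else "A"
                if ref in _CODE:
                    recs.append(VariantRecord(chrom=d.chrom, pos=pos, ref=ref, alt=alt,
                                              vclass="SNV", vaf=0.5))
        variants[s] = recs
        trees[s] = build_clone_tree(
            partition_variants(recs), _rng(seed, 16, i),
            clone_range=config.clone_range, branched_prob=config.branched_prob,
        )

    outcomes = {}
    event_times = {}
    for j, endpoint in enumerate(("OS", "DFS")):
        y, delta, T = draw_survival(eta.to_numpy(), config.baseline, config.censoring, _rng(seed, 17 + j))
        outcomes[endpoint] = [
            SurvivalRecord(sample=s, endpoint=endpoint, y=float(yi), delta=int(di))
            for s, yi, di in zip(samples, y, delta)
        ]
        event_times[endpoint] = T

    truth = GroundTruth(
        beta_true=dict(config.beta_true),
        covariates=covariates,
        eta=eta,
        rates=rates,
        event_times=event_times,
    )
    return SimulatedCohort(
        genome=genome, variants=variants, trees=trees,
        clinical=clinical, outcomes=outcomes, ground_truth=truth,
    )
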