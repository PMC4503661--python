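"""Seeded generators for every input class the pipeline consumes.

Each generator emulates one data class of a two-genotype budding-yeast
experiment: ChIP read sets with group-specific enrichment, spliced RNA-seq
reads with known per-junction splicing fraction, near-log-normal GFP
intensity distributions with genotype shifts, dual-luciferase plates with
known fidelity percentages, and logistic growth curves.  Alongside the data,
every generator returns a truth record; downstream recovery tests read truth
only from these records.

Determinism: every generator derives its random stream from
``(seed, stream_key)`` via :class:`numpy.random.SeedSequence`, so the same
seed reproduces identical outputs and adding one generator call never
perturbs another's stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cytometry_ks import CytometrySample
from .genomic_core import AlignedRead, GenomicInterval, TranscriptModel
from .growth import GrowthCurve
from .reporters import ReporterMeasurement
from .splicing_pso import SplicingUnit, units_from_annotation

_STREAMS = {"chip": 11, "rnaseq": 12, "cytometry": 13, "luciferase": 14, "growth": 15}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# Toy genome and annotation
# ---------------------------------------------------------------------------


def default_genome() -> dict[str, int]:
    """4 chromosomes x 100 kb: small enough for sub-minute test runs."""
    return {"chrI": 100_000, "chrII": 100_000, "chrIII": 100_000, "chrIV": 100_000}


def default_transcripts(
    n_genes: int = 60,
    n_spliced: int = 20,
    exon_length: int = 400,
    intron_length: int = 200,
    gene_length: int = 1000,
    spacing: int = 6000,
) -> dict[str, TranscriptModel]:
    """60 genes over the toy genome; the first 20 carry one intron each.

    Genes alternate strand and are spaced so that metagene windows and
    extended reads from neighbouring genes do not bleed into each other.
    """
    genome = list(default_genome().items())
    per_chrom = math.ceil(n_genes / len(genome))
    transcripts: dict[str, TranscriptModel] = {}
    idx = 0
    for chrom, _ in genome:
        for j in range(per_chrom):
            if idx >= n_genes:
                break
            start = 3000 + j * spacing
            strand = "+" if idx % 2 == 0 else "-"
            name = f"gene{idx + 1:03d}"
            if idx < n_spliced:
                exons = (
                    GenomicInterval(chrom, start, start + exon_length, strand),
                    GenomicInterval(
                        chrom,
                        start + exon_length + intron_length,
                        start + 2 * exon_length + intron_length,
                        strand,
                    ),
                )
            else:
                exons = (GenomicInterval(chrom, start, start + gene_length, strand),)
            transcripts[name] = TranscriptModel(name, exons)
            idx += 1
    return transcripts


# ---------------------------------------------------------------------------
# ChIP reads with group-specific enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChipSimConfig:
    genome: Mapping[str, int] = field(default_factory=default_genome)
    target_intervals: tuple[GenomicInterval, ...] = ()
    enrichment: float = 5.0
    depth: int = 200_000
    read_length: int = 36
    sample_id: str = "chip"


def gen_chip_reads(config: ChipSimConfig, seed: int = 0):
    """Background reads uniform over the genome; target intervals receive
    reads at ``enrichment`` x the background rate.  Returns (reads, truth)."""
    rng = _rng(seed, "chip")
    L = config.read_length
    chroms = sorted(config.genome)
    if config.depth == 0:
        return [], {"enrichment": config.enrichment, "depth": 0}
    # multinomial allocation over background (whole chroms) + target excess
    segments: list[tuple[str, int, int]] = [
        (c, 0, config.genome[c]) for c in chroms
    ]
    weights = [float(config.genome[c]) for c in chroms]
    for iv in config.target_intervals:
        segments.append((iv.chrom, iv.start, iv.end))
        weights.append((config.enrichment - 1.0) * len(iv))
    probs = np.asarray(weights) / np.sum(weights)
    counts = rng.multinomial(config.depth, probs)
    reads: list[AlignedRead] = []
    for (chrom, lo, hi), n in zip(segments, counts):
        if n == 0:
            continue
        max_start = hi - L
        if max_start < lo:
            raise ValueError(f"segment {chrom}:{lo}-{hi} shorter than read length")
        starts = rng.integers(lo, max_start + 1, size=n)
        strands = rng.choice(["+", "-"], size=n)
        for s, st in zip(starts, strands):
            iv = GenomicInterval(chrom, int(s), int(s) + L, str(st))
            reads.append(AlignedRead(interval=iv, sample_id=config.sample_id))
    truth = {
        "enrichment": config.enrichment,
        "depth": config.depth,
        "read_length": L,
        "n_targets": len(config.target_intervals),
    }
    return reads, truth


# ---------------------------------------------------------------------------
# Spliced RNA-seq reads with known splicing fraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplicedSimConfig:
    transcripts: Mapping[str, TranscriptModel] = field(default_factory=default_transcripts)
    theta: float | Mapping[str, float] = 0.5  # per-unit true splicing fraction
    reads_per_unit: int = 2000
    read_length: int = 50
    sample_id: str = "rna"


def expected_pso(
    exon1_len: int, intron_len: int, exon2_len: int, read_length: int, theta: float
) -> float:
    """Analytic expected PSO for one unit, by exhaustive position enumeration.

    Fragments are spliced with probability theta (read drawn uniformly over
    mRNA start positions; it spans the junction when it covers >= 1 base of
    each exon) or unspliced (read drawn uniformly over genomic start
    positions).  Expected PSO is 100 x E[junction reads] / E[exonic mean
    coverage] under this geometry; this is the oracle for recovery tests.
    """
    L = read_length
    e1, intr, e2 = exon1_len, intron_len, exon2_len
    m_len = e1 + e2
    t_len = e1 + intr + e2
    if L > m_len or L > t_len:
        raise ValueError("read length exceeds transcript span")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    spliced_starts = m_len - L + 1
    # junction-spanning mRNA starts: >= 1 base on each side of the junction
    lo, hi = max(0, e1 - L + 1), min(e1 - 1, m_len - L)
    junction_starts = max(0, hi - lo + 1)
    p_junction = theta * junction_starts / spliced_starts

    # exonic bases per read: spliced reads are fully exonic (= L)
    starts = np.arange(t_len - L + 1)
    ends = starts + L
    in_exon1 = np.clip(np.minimum(ends, e1) - starts, 0, None)
    in_exon2 = np.clip(ends - np.maximum(starts, e1 + intr), 0, None)
    in_exon2 = np.minimum(in_exon2, L)
    mean_exonic_unspliced = float(np.mean(in_exon1 + in_exon2))
    mean_exonic = theta * L + (1.0 - theta) * mean_exonic_unspliced
    exonic_cov_per_read = mean_exonic / (e1 + e2)
    return 100.0 * p_junction / exonic_cov_per_read


def _unit_theta(theta, unit_id: str) -> float:
    return float(theta[unit_id]) if isinstance(theta, Mapping) else float(theta)


def gen_spliced_reads(config: SplicedSimConfig, seed: int = 0):
    """Reads over every intron-containing transcript; returns (reads, truth).

    truth maps unit_id -> {theta, expected_pso, exon lengths}.
    """
    rng = _rng(seed, "rnaseq")
    units = units_from_annotation(config.transcripts)
    if not units:
        raise ValueError("no intron-containing transcripts to simulate")
    L = config.read_length
    reads: list[AlignedRead] = []
    truth: dict[str, dict] = {}
    for unit in units:
        left, right = sorted((unit.donor_exon, unit.acceptor_exon), key=lambda e: e.start)
        e1, e2, intr = len(left), len(right), unit.intron_length
        m_len, t_len = e1 + e2, e1 + intr + e2
        if L > m_len:
            raise ValueError(f"unit {unit.unit_id}: read length exceeds mRNA length")
        theta = _unit_theta(config.theta, unit.unit_id)
        spliced = rng.random(config.reads_per_unit) < theta
        for is_spliced in spliced:
            if is_spliced:
                s = int(rng.integers(0, m_len - L + 1))
                if s + L <= e1:  # fully in left exon
                    blocks = (GenomicInterval(unit.chrom, left.start + s, left.start + s + L, unit.strand),)
                elif s >= e1:  # fully in right exon
                    g = right.start + (s - e1)
                    blocks = (GenomicInterval(unit.chrom, g, g + L, unit.strand),)
                else:  # junction-spanning: two blocks with gap = intron
                    blocks = (
                        GenomicInterval(unit.chrom, left.start + s, left.end, unit.strand),
                        GenomicInterval(unit.chrom, right.start, right.start + (s + L - e1), unit.strand),
                    )
            else:
                s = int(rng.integers(0, t_len - L + 1))
                blocks = (GenomicInterval(unit.chrom, left.start + s, left.start + s + L, unit.strand),)
            iv = GenomicInterval(unit.chrom, blocks[0].start, blocks[-1].end, unit.strand)
            reads.append(AlignedRead(interval=iv, blocks=blocks, sample_id=config.sample_id))
        truth[unit.unit_id] = {
            "theta": theta,
            "expected_pso": expected_pso(e1, intr, e2, L, theta),
            "exon_lengths": (e1, e2),
            "intron_length": intr,
        }
    return reads, truth


# ---------------------------------------------------------------------------
# Cytometry intensities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CytometrySimConfig:
    """Log-normal GFP intensities; ~10,000 cells per replicate by default."""

    genotypes: tuple[str, ...] = ("WT", "mut")
    shift: tuple[float, ...] = (1.0, 1.5)  # multiplicative intensity factor
    n_cells: int = 10_000
    n_replicates: int = 2
    log_mean: float = math.log(500.0)
    log_sd: float = 0.5


def gen_cytometry(config: CytometrySimConfig, seed: int = 0) -> list[CytometrySample]:
    if len(config.shift) != len(config.genotypes):
        raise ValueError("one shift factor per genotype required")
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(seed, "cytometry")
    samples = []
    for genotype, factor in zip(config.genotypes, config.shift):
        for rep in range(1, config.n_replicates + 1):
            values = factor * rng.lognormal(
                mean=config.log_mean, sigma=config.log_sd, size=config.n_cells
            )
            samples.append(
                CytometrySample(
                    intensities=values, genotype=genotype, replicate_id=f"rep{rep}"
                )
            )
    return samples


# ---------------------------------------------------------------------------
# Luciferase plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LuciferaseSimConfig:
    """Plate truths are percentages on the analysis scale.

    ``ires_pct`` is relative to the first (reference) strain; frameshift and
    readthrough percentages are relative to that strain's own control wells.
    """

    strains: tuple[str, ...] = ("WT", "scc2-4")
    control_ratio: float = 5.0  # F/R of the 0-frame control
    sense_ratio: float = 2.0  # F/R of the sense-codon readthrough control
    ires_ratio_reference: float = 2.0
    fs_minus1_pct: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 1.1, "scc2-4": 3.4}
    )
    fs_plus1_pct: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.8, "scc2-4": 0.8}
    )
    readthrough_pct: Mapping[str, float] = field(
        default_factory=lambda: {"stop_UAA": 0.3, "stop_UAG": 0.6, "stop_UGA": 1.0}
    )
    ires_pct: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 100.0, "scc2-4": 55.0}
    )
    renilla_mean: float = 1e5
    cv: float = 0.10  # multiplicative (log-normal) noise on each luminescence
    n_replicates: int = 6


def _lognoise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def gen_luciferase(config: LuciferaseSimConfig, seed: int = 0):
    """Reporter wells for every strain and construct; returns (wells, truth)."""
    if config.cv < 0:
        raise ValueError("cv must be >= 0")
    rng = _rng(seed, "luciferase")
    wells: list[ReporterMeasurement] = []
    n = config.n_replicates

    def add(strain: str, role: str, true_ratio: float) -> None:
        renilla = config.renilla_mean * _lognoise(rng, config.cv, n)
        firefly = renilla * true_ratio * _lognoise(rng, config.cv, n)
        for i, (f, r) in enumerate(zip(firefly, renilla), start=1):
            wells.append(
                ReporterMeasurement(
                    firefly=float(f), renilla=float(r), construct_role=role,
                    strain=strain, replicate_id=f"rep{i}",
                )
            )

    for strain in config.strains:
        add(strain, "zero_frame_control", config.control_ratio)
        add(strain, "minus1_PRF", config.control_ratio * config.fs_minus1_pct[strain] / 100.0)
        add(strain, "plus1_PRF", config.control_ratio * config.fs_plus1_pct[strain] / 100.0)
        add(strain, "sense_control", config.sense_ratio)
        for stop, pct in config.readthrough_pct.items():
            add(strain, stop, config.sense_ratio * pct / 100.0)
        add(strain, "IRES", config.ires_ratio_reference * config.ires_pct[strain] / 100.0)

    truth = {
        "fs_minus1_pct": dict(config.fs_minus1_pct),
        "fs_plus1_pct": dict(config.fs_plus1_pct),
        "readthrough_pct": dict(config.readthrough_pct),
        "ires_pct": dict(config.ires_pct),
    }
    return wells, truth


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthSimConfig:
    """Logistic growth with additive Gaussian OD noise.

    Defaults model an overnight plate-reader yeast culture in rich medium:
    inoculation at OD 0.05, saturation near OD 2, readings every 30 min for
    24 h (a 5-point fitting window then spans 2 h, roughly 1.7 doublings at
    the wild-type rate, so log-linear fits are signal- rather than
    noise-dominated).
    """

    rates: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.6, "scc2-4": 0.42}
    )  # per hour
    carrying_capacity: float = 2.0
    n0: float = 0.05
    sigma: float = 0.005
    t_max_min: float = 1440.0
    dt_min: float = 30.0
    condition: str = "YPD"
    n_replicates: int = 3


def logistic_od(t_hours, r: float, carrying_capacity: float, n0: float) -> np.ndarray:
    """Closed-form logistic OD(t) = K N0 / (N0 + (K - N0) e^{-rt})."""
    t = np.asarray(t_hours, dtype=np.float64)
    K = carrying_capacity
    return K * n0 / (n0 + (K - n0) * np.exp(-r * t))


def gen_growth(config: GrowthSimConfig, seed: int = 0):
    """Noisy logistic curves per strain/replicate; returns (curves, truth)."""
    for name, r in config.rates.items():
        if r <= 0 or config.carrying_capacity <= 0 or config.n0 <= 0:
            raise ValueError("r, K and N0 must all be > 0")
    rng = _rng(seed, "growth")
    times = np.arange(0.0, config.t_max_min + config.dt_min / 2, config.dt_min)
    curves: list[GrowthCurve] = []
    for strain in sorted(config.rates):
        r = config.rates[strain]
        clean = logistic_od(times / 60.0, r, config.carrying_capacity, config.n0)
        for rep in range(1, config.n_replicates + 1):
            noisy = clean + rng.normal(0.0, config.sigma, size=times.size)
            curves.append(
                GrowthCurve(
                    times=times.copy(), od=noisy, strain=strain,
                    condition=config.condition, replicate_id=f"rep{rep}",
                )
            )
    truth = {
        "rates": dict(config.rates),
        "carrying_capacity": config.carrying_capacity,
        "n0": config.n0,
        "sigma": config.sigma,
    }
    return curves, truth


# ---------------------------------------------------------------------------
# Aggregate configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """All study conditions for an end-to-end synthetic run."""

    seed: int = 0
    chip: ChipSimConfig = field(default_factory=ChipSimConfig)
    spliced: SplicedSimConfig = field(default_factory=SplicedSimConfig)
    cytometry: CytometrySimConfig = field(default_factory=CytometrySimConfig)
    luciferase: LuciferaseSimConfig = field(default_factory=LuciferaseSimConfig)
    growth: GrowthSimConfig = field(default_factory=GrowthSimConfig)
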