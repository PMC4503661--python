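"""Percent-Spliced-Out (PSO) splicing efficiency from split-read evidence.

A splicing unit is one annotated intron with its two flanking exons.  PSO is
the junction coverage (split reads whose inner gap exactly matches the
intron) divided by the mean per-base coverage over the two flanking exons,
times 100.  Because the numerator is a read count and the denominator a mean
per-base depth, deep junction support over short exons can push PSO above
100; values are deliberately not capped.

Differences in PSO between genotypes are assessed with a one-way
fixed-effects ANOVA per unit, and p-values are Benjamini-Hochberg adjusted
across all tested units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_stats import bh_adjust
from .genomic_core import AlignedRead, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

#: Units whose exonic coverage falls below this read-per-base equivalent are
#: flagged low-confidence (still reported).
LOW_COVERAGE_THRESHOLD = 1.0


@dataclass(frozen=True)
class SplicingUnit:
    """One annotated intron with its two flanking exons.

    Donor/acceptor are in transcription sense; coordinates are genomic, so on
    the - strand the donor exon is the rightmost of the pair.  ``junction`` is
    the (gap_start, gap_end) half-open genomic span of the intron.
    """

    unit_id: str
    donor_exon: GenomicInterval
    acceptor_exon: GenomicInterval

    def __post_init__(self) -> None:
        d, a = self.donor_exon, self.acceptor_exon
        if d.chrom != a.chrom or d.strand != a.strand:
            raise ValueError(f"unit {self.unit_id}: exons on different chrom/strand")
        left, right = (d, a) if d.start <= a.start else (a, d)
        if left.end >= right.start:
            raise ValueError(f"unit {self.unit_id}: exons overlap or touch (no intron)")

    @property
    def chrom(self) -> str:
        return self.donor_exon.chrom

    @property
    def strand(self) -> str:
        return self.donor_exon.strand

    @property
    def junction(self) -> tuple[int, int]:
        left, right = sorted((self.donor_exon, self.acceptor_exon), key=lambda e: e.start)
        return (left.end, right.start)

    @property
    def intron_length(self) -> int:
        gap = self.junction
        return gap[1] - gap[0]

    @property
    def exonic_length(self) -> int:
        return len(self.donor_exon) + len(self.acceptor_exon)


@dataclass
class PsoResult:
    unit_id: str
    pso_by_sample: dict[str, float]
    f_stat: float
    p: float
    adj_p: float


def units_from_annotation(
    transcripts: Mapping[str, TranscriptModel]
) -> list[SplicingUnit]:
    """One unit per annotated intron; intronless transcripts yield none."""
    units: list[SplicingUnit] = []
    for tid in sorted(transcripts):
        tx = transcripts[tid]
        exons = tx.exons
        for i in range(len(exons) - 1):
            if exons[i].end >= exons[i + 1].start:
                raise ValueError(f"transcript {tid}: overlapping exons")
        # exon order in transcription sense
        ordered = exons if tx.strand != "-" else exons[::-1]
        for i in range(len(ordered) - 1):
            units.append(
                SplicingUnit(
                    unit_id=f"{tid}.intron{i + 1}",
                    donor_exon=ordered[i],
                    acceptor_exon=ordered[i + 1],
                )
            )
    return units


def junction_support(
    reads: Iterable[AlignedRead], unit: SplicingUnit, tolerance: int = 0
) -> int:
    """Count split reads with two consecutive blocks whose inner gap matches
    the unit's intron (exactly by default; ``tolerance`` allows +-N bp)."""
    gap_start, gap_end = unit.junction
    n = 0
    for read in reads:
        if not read.is_split or read.interval.chrom != unit.chrom:
            continue
        for left, right in zip(read.blocks, read.blocks[1:]):
            if (
                abs(left.end - gap_start) <= tolerance
                and abs(right.start - gap_end) <= tolerance
            ):
                n += 1
                break
    return n


def exonic_unit_coverage(reads: Iterable[AlignedRead], unit: SplicingUnit) -> float:
    """Mean per-base block coverage over the two flanking exons."""
    total_len = unit.exonic_length
    if total_len <= 0:
        raise ValueError(f"unit {unit.unit_id}: zero exonic length")
    covered = 0
    for read in reads:
        for b in read.blocks:
            covered += b.overlap_length(unit.donor_exon)
            covered += b.overlap_length(unit.acceptor_exon)
    return covered / total_len


def pso(junction_cov: float, exonic_cov: float) -> float:
    """PSO percent = 100 x junction coverage / exonic coverage.

    Returns NaN (missing, reason: no coverage) when exonic coverage is zero;
    a zero denominator is never reported as 0% splicing.
    """
    if exonic_cov < 0:
        raise ValueError("exonic coverage must be >= 0")
    if exonic_cov == 0:
        logger.info("PSO undefined (no coverage)")
        return float("nan")
    return 100.0 * junction_cov / exonic_cov


def compute_pso_table(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    units: Sequence[SplicingUnit],
    tolerance: int = 0,
) -> pd.DataFrame:
    """PSO per unit (rows) x sample (columns); adds a low_confidence flag
    column set when any sample's exonic coverage is below
    :data:`LOW_COVERAGE_THRESHOLD` reads per base."""
    rows = {}
    low_conf = {}
    for unit in units:
        vals = {}
        low = False
        for sample, reads in reads_by_sample.items():
            jc = junction_support(reads, unit, tolerance=tolerance)
            ec = exonic_unit_coverage(reads, unit)
            if 0 < ec < LOW_COVERAGE_THRESHOLD:
                low = True
            vals[sample] = pso(jc, ec)
        rows[unit.unit_id] = vals
        low_conf[unit.unit_id] = low
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "unit_id"
    df["low_confidence"] = pd.Series(low_conf)
    return df


def pso_anova(
    pso_table: pd.DataFrame, genotypes: Mapping[str, str]
) -> pd.DataFrame:
    """One-way ANOVA of PSO across genotypes per unit, BH across units.

    ``pso_table`` has units as rows and sample columns; ``genotypes`` maps
    sample -> genotype label.  Units with any missing PSO are dropped with a
    logged reason.  Requires >= 2 genotypes with >= 2 replicates each.
    """
    samples = [c for c in pso_table.columns if c in genotypes]
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(genotypes[s], []).append(s)
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 genotypes")
    for g, ss in groups.items():
        if len(ss) < 2:
            raise ValueError(f"genotype {g!r} has < 2 replicates")

    unit_ids, f_stats, p_vals = [], [], []
    for unit_id, row in pso_table[samples].iterrows():
        if row.isna().any():
            logger.info("unit %s dropped: missing PSO in >= 1 sample", unit_id)
            continue
        arrays = [row[ss].to_numpy(dtype=np.float64) for ss in groups.values()]
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0.0:
            # no between-group variance: F = 0 by definition, p = 1
            f, p = 0.0, 1.0
        else:
            with np.errstate(all="ignore"):
                f, p = stats.f_oneway(*arrays)
            if not np.isfinite(f):
                f, p = 0.0, 1.0
        unit_ids.append(unit_id)
        f_stats.append(float(f))
        p_vals.append(float(p))

    out = pd.DataFrame({"f_stat": f_stats, "p": p_vals}, index=pd.Index(unit_ids, name="unit_id"))
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
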