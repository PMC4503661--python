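"""Core genomic data model: intervals, aligned reads, coverage and feature counting.

All coordinates are 0-based half-open internally.  BED input is taken as-is;
GFF3/GTF coordinates (1-based inclusive) are converted on read, so a GFF exon
``start=101 end=200`` becomes the internal interval ``[100, 200)``.

The atomic evidence unit is :class:`AlignedRead`: one mapped read with an
optional block structure.  A read with more than one block is a split
(junction-spanning) read; contiguous ChIP reads have a single block.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")

#: Default ChIP fragment length reads are extended to before computing coverage.
DEFAULT_EXTENSION = 150


class AnnotationParseError(ValueError):
    """An annotation file could not be parsed; the message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read; ``blocks`` carries split-read structure (>=1 block).

    Blocks must be sorted, non-overlapping and contained in ``interval``.
    A single-block read is a contiguous alignment (the ChIP case); gaps
    between consecutive blocks are the spliced-out segments (the RNA case).
    """

    interval: GenomicInterval
    blocks: tuple[GenomicInterval, ...] = ()
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            object.__setattr__(self, "blocks", (self.interval,))
        blocks = self.blocks
        prev_end = None
        for b in blocks:
            if b.chrom != self.interval.chrom or b.strand != self.interval.strand:
                raise ValueError("blocks must share the read's chrom and strand")
            if b.start < self.interval.start or b.end > self.interval.end:
                raise ValueError("blocks must be contained in the read interval")
            if prev_end is not None and b.start < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = b.end
        if sum(len(b) for b in blocks) > len(self.interval):
            raise ValueError("union of block lengths exceeds interval length")

    @property
    def is_split(self) -> bool:
        return len(self.blocks) > 1

    @property
    def aligned_length(self) -> int:
        return sum(len(b) for b in self.blocks)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: >=1 exon on one chrom/strand; the TSS is strand-aware."""

    transcript_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: needs >= 1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple chroms/strands"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """0-based position of the 5'-most transcribed base (strand-aware)."""
        if self.strand == "-":
            return self.exons[-1].end - 1
        return self.exons[0].start

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


# ---------------------------------------------------------------------------
# Annotation input
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return "bed"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    if suffix == ".gtf":
        return "gtf"
    raise ValueError(f"cannot infer annotation format from {path.name!r}; pass fmt=")


def load_annotation(path, fmt: str | None = None) -> dict[str, TranscriptModel]:
    """Read transcript models from BED6/BED12, GFF3 or GTF.

    GFF/GTF coordinates are converted from 1-based inclusive to the internal
    0-based half-open convention.  Returns a dict keyed by transcript ID.
    """
    path = Path(path)
    fmt = (fmt or _infer_format(path)).lower()
    if fmt == "bed":
        return _load_bed_annotation(path)
    if fmt in ("gff3", "gtf"):
        return _load_gff_annotation(path, dialect=fmt)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _load_bed_annotation(path: Path) -> dict[str, TranscriptModel]:
    transcripts: dict[str, TranscriptModel] = {}
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise AnnotationParseError(
                    f"{path.name} line {lineno}: expected >= 3 BED fields"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
                strand = fields[5] if len(fields) > 5 else "."
                if strand not in VALID_STRANDS:
                    raise ValueError(f"bad strand {strand!r}")
                if len(fields) >= 12:
                    exons = _bed12_blocks(chrom, start, end, strand, fields)
                else:
                    exons = (GenomicInterval(chrom, start, end, strand),)
            except (ValueError, IndexError) as exc:
                raise AnnotationParseError(
                    f"{path.name} line {lineno}: {exc}"
                ) from exc
            for e in exons:
                if e.start < start or e.end > end:
                    raise AnnotationParseError(
                        f"{path.name} line {lineno}: block outside declared span"
                    )
            if name in transcripts:
                raise AnnotationParseError(
                    f"{path.name} line {lineno}: duplicate feature ID {name!r}"
                )
            transcripts[name] = TranscriptModel(name, exons)
            n_data += 1
    if n_data == 0:
        warnings.warn(f"{path.name}: no features found", stacklevel=2)
        logger.warning("%s: empty annotation", path)
    return transcripts


def _bed12_blocks(chrom, start, end, strand, fields) -> tuple[GenomicInterval, ...]:
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError("blockSizes/blockStarts length mismatch with blockCount")
    return tuple(
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(offsets, sizes)
    )


def _load_gff_annotation(path: Path, dialect: str) -> dict[str, TranscriptModel]:
    import gffutils

    with open(path) as fh:
        has_data = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_data:
        warnings.warn(f"{path.name}: no features found", stacklevel=3)
        logger.warning("%s: empty annotation", path)
        return {}
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationParseError(f"{path.name}: {exc}") from exc

    parents: dict[str, GenomicInterval] = {}
    for ftype in ("mRNA", "transcript", "gene"):
        for feat in db.features_of_type(ftype):
            parents.setdefault(
                feat.id, GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )

    exons_by_parent: dict[str, list[GenomicInterval]] = {}
    for exon in db.features_of_type("exon"):
        if dialect == "gtf":
            pids = exon.attributes.get("transcript_id", [])
        else:
            pids = exon.attributes.get("Parent", [])
        if not pids:
            raise AnnotationParseError(
                f"{path.name}: exon at {exon.seqid}:{exon.start} has no parent"
            )
        ival = GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
        for pid in pids:
            parent_span = parents.get(pid)
            if parent_span is not None and (
                ival.start < parent_span.start or ival.end > parent_span.end
            ):
                raise AnnotationParseError(
                    f"{path.name}: exon {exon.seqid}:{exon.start}-{exon.end} "
                    f"outside span of parent {pid!r}"
                )
            exons_by_parent.setdefault(pid, []).append(ival)

    transcripts = {
        pid: TranscriptModel(pid, tuple(exons)) for pid, exons in exons_by_parent.items()
    }
    if not transcripts:
        warnings.warn(f"{path.name}: no exon features found", stacklevel=3)
    return transcripts


# ---------------------------------------------------------------------------
# Read ingestion
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV ``chrom<TAB>length``."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise AnnotationParseError(f"chrom sizes line {lineno}: need 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def reads_from_bed(path, sample_id: str | None = None) -> list[AlignedRead]:
    """Read alignments from BED6/BED12; BED12 blocks become split-read blocks."""
    path = Path(path)
    sample = sample_id if sample_id is not None else path.stem
    reads = []
    for name, tx in _load_bed_annotation(path).items():
        reads.append(AlignedRead(interval=tx.span, blocks=tx.exons, sample_id=sample))
    return reads


def write_reads_bed(reads: Iterable[AlignedRead], path) -> None:
    """Write alignments as BED12 (blocks preserve split-read structure)."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            iv = read.interval
            sizes = ",".join(str(len(b)) for b in read.blocks)
            offsets = ",".join(str(b.start - iv.start) for b in read.blocks)
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{read.sample_id or 'read'}_{i}\t0\t"
                f"{strand}\t{iv.start}\t{iv.end}\t0\t{len(read.blocks)}\t{sizes}\t{offsets}\n"
            )


def reads_from_bam(path, sample_id: str | None = None, min_mapq: int | None = None) -> list[AlignedRead]:
    """Read mapped alignments from a BAM/SAM file via pysam.

    Alignments are taken as-is (no MAPQ filter) unless ``min_mapq`` is given;
    mates of a pair are treated as independent reads.  Secondary and
    supplementary records are skipped.
    """
    import pysam

    path = Path(path)
    sample = sample_id if sample_id is not None else path.stem
    reads: list[AlignedRead] = []
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if min_mapq is not None and aln.mapping_quality < min_mapq:
                continue
            strand = "-" if aln.is_reverse else "+"
            blocks = tuple(
                GenomicInterval(aln.reference_name, s, e, strand)
                for s, e in aln.get_blocks()
            )
            interval = GenomicInterval(
                aln.reference_name, blocks[0].start, blocks[-1].end, strand
            )
            reads.append(AlignedRead(interval=interval, blocks=blocks, sample_id=sample))
    return reads


# ---------------------------------------------------------------------------
# Read extension (ChIP fragments)
# ---------------------------------------------------------------------------


def extend_read(
    read: AlignedRead,
    target_len: int = DEFAULT_EXTENSION,
    chrom_sizes: Mapping[str, int] | None = None,
) -> AlignedRead:
    """Extend a contiguous read to ``target_len`` bp in the 3' direction.

    The 5' coordinate is the anchor: on + (or unstranded) reads the start is
    fixed and the end grows; on - reads the end is fixed and the start shrinks.
    Reads already >= ``target_len`` are returned unchanged.  Extension is
    clipped at chromosome bounds when ``chrom_sizes`` is provided.
    """
    if read.is_split:
        raise ValueError("cannot extend a split (multi-block) read")
    if target_len <= 0:
        raise ValueError("target_len must be > 0")
    iv = read.interval
    if len(iv) >= target_len:
        return read
    if iv.strand == "-":
        start, end = iv.end - target_len, iv.end
        start = max(0, start)
    else:
        start, end = iv.start, iv.start + target_len
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[iv.chrom])
    new_iv = GenomicInterval(iv.chrom, start, end, iv.strand)
    return AlignedRead(interval=new_iv, blocks=(new_iv,), sample_id=read.sample_id)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Per-chromosome per-base coverage; ``units`` is 'raw' or 'rpm'."""

    data: dict[str, np.ndarray]
    units: str = "raw"
    library_size: int | None = None

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))


def coverage_from_reads(
    reads: Iterable[AlignedRead], chrom_sizes: Mapping[str, int]
) -> CoverageTrack:
    """Raw per-base coverage: value at base b = number of read blocks overlapping b.

    Blocks reaching beyond the chromosome end are clipped with a warning.
    The genome-wide sum equals the summed (clipped) block lengths.
    """
    deltas = {chrom: np.zeros(size + 1, dtype=np.int64) for chrom, size in chrom_sizes.items()}
    n_reads = 0
    n_clipped = 0
    for read in reads:
        n_reads += 1
        for b in read.blocks:
            if b.chrom not in deltas:
                raise KeyError(f"read on undeclared chromosome {b.chrom!r}")
            size = chrom_sizes[b.chrom]
            start, end = b.start, min(b.end, size)
            if b.end > size:
                n_clipped += 1
            if end <= start:
                continue
            deltas[b.chrom][start] += 1
            deltas[b.chrom][end] -= 1
    if n_clipped:
        warnings.warn(f"{n_clipped} block(s) clipped at chromosome ends", stacklevel=2)
    data = {
        chrom: np.cumsum(d[:-1]).astype(np.float64) for chrom, d in deltas.items()
    }
    return CoverageTrack(data=data, units="raw", library_size=n_reads)


def rpm_normalize(track: CoverageTrack, library_size: int | None = None) -> CoverageTrack:
    """Scale a raw track by 1e6 / library_size (reads per million)."""
    size = library_size if library_size is not None else track.library_size
    if size is None or size <= 0:
        raise ValueError("library_size must be a positive integer")
    factor = 1e6 / size
    data = {chrom: arr * factor for chrom, arr in track.data.items()}
    return CoverageTrack(data=data, units="rpm", library_size=size)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track as BedGraph (runs of equal value collapsed)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, chrom_sizes: Mapping[str, int], units: str = "rpm") -> CoverageTrack:
    data = {chrom: np.zeros(size, dtype=np.float64) for chrom, size in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise AnnotationParseError(f"bedgraph line {lineno}: need 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in data:
                raise KeyError(f"bedgraph line {lineno}: undeclared chromosome {chrom!r}")
            data[chrom][start:end] = value
    return CoverageTrack(data=data, units=units)


# ---------------------------------------------------------------------------
# Feature counting and RPKM
# ---------------------------------------------------------------------------


@dataclass
class FeatureCountTable:
    """Read counts per feature (rows, lexicographic) x sample (columns)."""

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series

    def rpkm(self) -> pd.DataFrame:
        """RPKM = count x 1e9 / (length_bp x library_size), per sample."""
        return (
            self.counts
            * 1e9
            / np.outer(self.lengths.to_numpy(), self.library_sizes.to_numpy())
        )


def _normalize_features(features) -> list[tuple[str, GenomicInterval]]:
    if isinstance(features, Mapping):
        items = list(features.items())
    else:
        items = list(features)
    out = []
    seen = set()
    for fid, obj in items:
        if fid in seen:
            raise ValueError(f"duplicate feature ID {fid!r}")
        seen.add(fid)
        iv = obj.span if isinstance(obj, TranscriptModel) else obj
        out.append((fid, iv))
    return out


def count_reads_per_feature(
    reads: Iterable[AlignedRead],
    features: Mapping[str, GenomicInterval] | Sequence[tuple[str, GenomicInterval]],
) -> FeatureCountTable:
    """Count reads per feature: any >=1 bp block overlap increments the feature.

    A read overlapping k features increments all k.  Library size per sample
    is the total number of reads from that sample (mapped input), counted
    whether or not they hit a feature.
    """
    items = _normalize_features(features)
    trees: dict[str, IntervalTree] = {}
    for fid, iv in items:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, fid)

    feature_ids = sorted(fid for fid, _ in items)
    counts: dict[str, dict[str, int]] = {}
    library: dict[str, int] = {}
    for read in reads:
        sample = read.sample_id or "sample"
        library[sample] = library.get(sample, 0) + 1
        hit: set[str] = set()
        for b in read.blocks:
            tree = trees.get(b.chrom)
            if tree is not None:
                hit.update(h.data for h in tree.overlap(b.start, b.end))
        col = counts.setdefault(sample, {})
        for fid in hit:
            col[fid] = col.get(fid, 0) + 1

    samples = sorted(library) or ["sample"]
    mat = pd.DataFrame(0, index=feature_ids, columns=samples, dtype=np.int64)
    for sample, col in counts.items():
        for fid, n in col.items():
            mat.loc[fid, sample] = n
    lengths = pd.Series({fid: len(iv) for fid, iv in items}).loc[feature_ids]
    libsizes = pd.Series({s: library.get(s, 0) for s in samples})
    return FeatureCountTable(counts=mat, lengths=lengths, library_sizes=libsizes)


def rpkm(count: float, feature_len_bp: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if feature_len_bp <= 0 or library_size <= 0:
        raise ValueError("feature length and library size must be positive")
    return count * 1e9 / (feature_len_bp * library_size)
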