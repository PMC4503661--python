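"""Metagene profiles: strand-aware averaging of RPM coverage around anchors.

For a group of genes, RPM coverage is extracted for a fixed window on either
side of each gene's anchor (the TSS by default) and averaged per base pair
across the group.  Offsets are oriented 5'->3' in the transcription sense, so
negative offsets are upstream of the gene regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_core import CoverageTrack, TranscriptModel

DEFAULT_WINDOW = 600


@dataclass(frozen=True)
class AnchorSet:
    """Anchor positions (chrom, 0-based position, strand) for one gene group."""

    anchors: tuple[tuple[str, int, str], ...]
    group_name: str = ""

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError(f"anchor set {self.group_name!r} is empty")

    @property
    def n_features(self) -> int:
        return len(self.anchors)


@dataclass
class MetageneProfile:
    """Per-offset mean RPM coverage for a gene group around its anchors."""

    offsets: np.ndarray
    mean_rpm: np.ndarray
    group_name: str
    n_features: int
    sample_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_name,
                "sample": self.sample_id,
                "offset": self.offsets,
                "mean_rpm": self.mean_rpm,
            }
        )


def anchors_from_annotation(
    transcripts: Mapping[str, TranscriptModel],
    group_ids: Sequence[str],
    group_name: str = "",
) -> AnchorSet:
    """TSS anchors for the named transcripts; unresolved IDs raise KeyError."""
    missing = [gid for gid in group_ids if gid not in transcripts]
    if missing:
        raise KeyError(f"unresolved feature IDs: {', '.join(sorted(missing))}")
    if not group_ids:
        raise ValueError("empty gene group")
    anchors = tuple(
        (transcripts[gid].chrom, transcripts[gid].tss, transcripts[gid].strand)
        for gid in group_ids
    )
    return AnchorSet(anchors=anchors, group_name=group_name)


def extract_window(
    track: CoverageTrack, chrom: str, anchor: int, strand: str = "+", window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Coverage values at offsets -window..+window around an anchor.

    Positions falling outside the chromosome contribute 0 (and still count in
    any downstream average).  For - strand anchors the vector is reversed so
    that offset -window is upstream in the transcription sense.
    """
    arr = track[chrom]
    if anchor < 0 or anchor >= arr.size:
        raise ValueError(f"anchor {anchor} outside chromosome {chrom!r} (len {arr.size})")
    lo, hi = anchor - window, anchor + window + 1
    out = np.zeros(2 * window + 1, dtype=np.float64)
    src_lo, src_hi = max(lo, 0), min(hi, arr.size)
    out[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
    if strand == "-":
        out = out[::-1]
    return out


def metagene_profile(
    track: CoverageTrack,
    anchors: AnchorSet,
    window: int = DEFAULT_WINDOW,
    sample_id: str = "",
) -> MetageneProfile:
    """Mean coverage per offset over all anchors of a group."""
    acc = np.zeros(2 * window + 1, dtype=np.float64)
    for chrom, pos, strand in anchors.anchors:
        acc += extract_window(track, chrom, pos, strand, window)
    return MetageneProfile(
        offsets=np.arange(-window, window + 1),
        mean_rpm=acc / anchors.n_features,
        group_name=anchors.group_name,
        n_features=anchors.n_features,
        sample_id=sample_id,
    )


def profiles_to_frame(profiles: Iterable[MetageneProfile]) -> pd.DataFrame:
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
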