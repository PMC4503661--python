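"""ECDFs, Kolmogorov-Smirnov distances and the replicate-baseline shift test.

Fluorescence-intensity distributions from flow cytometry are non-Gaussian,
so distribution shifts between genotypes are measured with the KS distance
D = sup |F_a - F_b| between empirical CDFs.  With ~10,000 cells per sample
the KS test is significant for trivial shifts; the decision rule therefore
also demands an effect size: every between-genotype distance must exceed the
largest within-genotype (replicate) distance before a shift is flagged.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats


@dataclass
class CytometrySample:
    """A vector of per-cell fluorescence intensities for one replicate."""

    intensities: np.ndarray
    genotype: str
    replicate_id: str

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.size < 1:
            raise ValueError("sample must contain >= 1 cell")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(self.intensities.size)

    def gated(self, threshold: float = 0.0) -> np.ndarray:
        """Values above the GFP-positive gate (default 0 = no gate)."""
        return self.intensities[self.intensities > threshold]


class Ecdf:
    """Right-continuous empirical CDF: F(x) = fraction of values <= x."""

    def __init__(self, values) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.size == 0:
            raise ValueError("cannot build an ECDF from an empty sample")
        self._sorted = np.sort(values)
        self._n = values.size

    def __call__(self, x):
        result = np.searchsorted(self._sorted, np.asarray(x, dtype=np.float64), side="right") / self._n
        return float(result) if result.ndim == 0 else result


def ecdf(sample) -> Ecdf:
    values = sample.intensities if isinstance(sample, CytometrySample) else sample
    return Ecdf(values)


def ks_distance(sample_a, sample_b) -> float:
    """D = sup over observed values of |F_a(x) - F_b(x)|."""
    a = np.sort(np.asarray(sample_a.intensities if isinstance(sample_a, CytometrySample) else sample_a, dtype=np.float64))
    b = np.sort(np.asarray(sample_b.intensities if isinstance(sample_b, CytometrySample) else sample_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def _values(sample) -> np.ndarray:
    return np.asarray(
        sample.intensities if isinstance(sample, CytometrySample) else sample,
        dtype=np.float64,
    )


def ks_test(sample_a, sample_b, mode: str = "auto") -> float:
    """Two-sided two-sample KS p-value.

    ``exact_small`` uses the exact null distribution and is permitted only
    for n*m <= 1e4 (and falls back to asymptotic when ties are present);
    ``asymptotic`` uses the Kolmogorov limit with effective n = nm/(n+m).
    """
    a, b = _values(sample_a), _values(sample_b)
    if mode not in ("auto", "exact_small", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = False
    if mode in ("auto", "exact_small"):
        small = a.size * b.size <= 10_000
        if mode == "exact_small" and not small:
            raise ValueError("exact_small permitted only when n*m <= 1e4")
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        if small and not ties:
            use_exact = True
        elif mode == "exact_small" and ties:
            warnings.warn("ties present: falling back to asymptotic KS p", stacklevel=2)
    if use_exact:
        return float(stats.ks_2samp(a, b, method="exact").pvalue)
    # Kolmogorov limit with effective sample size nm/(n+m)
    d = ks_distance(a, b)
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    return float(min(1.0, special.kolmogorov(en * d)))


@dataclass
class KsComparison:
    sample_a: str
    sample_b: str
    d: float
    p: float
    comparison_class: str  # within_genotype | between_genotype


@dataclass
class BaselineDecision:
    """Outcome of the replicate-baseline test for one genotype pair."""

    genotype_a: str
    genotype_b: str
    within_d: list[float]
    between: list[KsComparison]
    alpha: float
    max_within_d: float = field(init=False)
    min_between_d: float = field(init=False)
    shift: bool = field(init=False)

    def __post_init__(self) -> None:
        self.max_within_d = max(self.within_d)
        self.min_between_d = min(c.d for c in self.between)
        self.shift = (
            all(c.d > self.max_within_d for c in self.between)
            and all(c.p < self.alpha for c in self.between)
        )


def replicate_baseline_test(
    samples: Sequence[CytometrySample],
    alpha: float = 0.05,
    gate: float = 0.0,
    mode: str = "asymptotic",
) -> list[BaselineDecision]:
    """Flag genotype pairs whose distributions have shifted beyond replicate noise.

    All within-genotype replicate distances form the baseline; a shift is
    flagged for a genotype pair when every between-genotype distance exceeds
    the largest within-genotype distance AND every between-pair KS p < alpha.
    Every genotype needs >= 2 replicates (otherwise there is no baseline).
    """
    by_genotype: dict[str, list[CytometrySample]] = {}
    for s in samples:
        by_genotype.setdefault(s.genotype, []).append(s)
    for g, ss in by_genotype.items():
        if len(ss) < 2:
            raise ValueError(f"genotype {g!r} has a single replicate: no baseline")

    gated = {
        (s.genotype, s.replicate_id): s.gated(gate) for s in samples
    }
    within: dict[str, list[float]] = {}
    for g, ss in by_genotype.items():
        within[g] = [
            ks_distance(gated[(g, x.replicate_id)], gated[(g, y.replicate_id)])
            for x, y in itertools.combinations(ss, 2)
        ]

    decisions = []
    for ga, gb in itertools.combinations(sorted(by_genotype), 2):
        between = []
        for x in by_genotype[ga]:
            for y in by_genotype[gb]:
                va, vb = gated[(ga, x.replicate_id)], gated[(gb, y.replicate_id)]
                between.append(
                    KsComparison(
                        sample_a=f"{ga}:{x.replicate_id}",
                        sample_b=f"{gb}:{y.replicate_id}",
                        d=ks_distance(va, vb),
                        p=ks_test(va, vb, mode=mode),
                        comparison_class="between_genotype",
                    )
                )
        decisions.append(
            BaselineDecision(
                genotype_a=ga,
                genotype_b=gb,
                within_d=within[ga] + within[gb],
                between=between,
                alpha=alpha,
            )
        )
    return decisions
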