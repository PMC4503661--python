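"""Dual-luciferase translational-fidelity calculators.

Each well yields a firefly/renilla (F/R) luminescence ratio; renilla is the
internal cap-dependent control, so F/R is insensitive to lysate amount and
plate gain.  Three derived quantities, all percentages:

* frameshifting efficiency: F/R of a programmed-frameshift construct (-1
  L-A virus signal, +1 Ty1 signal) relative to the 0-frame control, x100;
* stop-codon readthrough: F/R of a stop-codon reporter relative to the
  matching sense-codon reporter, x100 (100% = no termination);
* IRES activity: F/R of the IRES reporter in a strain relative to the
  reference (wild-type) strain, x100.

The default aggregation is the ratio of replicate-mean F/R ratios; a paired
per-replicate mode is available for plates with matched well layouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

CONSTRUCT_ROLES = (
    "zero_frame_control",
    "minus1_PRF",
    "plus1_PRF",
    "stop_UAA",
    "stop_UAG",
    "stop_UGA",
    "sense_control",
    "IRES",
    "IRES_mutant",
)


@dataclass(frozen=True)
class ReporterMeasurement:
    """One well: firefly/renilla luminescence with its construct and strain."""

    firefly: float
    renilla: float
    construct_role: str
    strain: str
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.construct_role not in CONSTRUCT_ROLES:
            raise ValueError(
                f"unknown construct role {self.construct_role!r}; expected one of {CONSTRUCT_ROLES}"
            )


@dataclass
class FidelityResult:
    quantity: str  # ires_activity_pct | fs_efficiency_pct | readthrough_pct
    value: float
    strain: str
    n_replicates: int
    sem: float


def fl_ratio(m: ReporterMeasurement) -> float:
    """Firefly / renilla luminescence ratio for one well."""
    if m.renilla <= 0:
        raise ValueError("renilla luminescence must be > 0 for a ratio")
    return m.firefly / m.renilla


def _check_same_strain(*sets: Sequence[ReporterMeasurement]) -> str:
    strains = {m.strain for ms in sets for m in ms}
    if len(strains) != 1:
        raise ValueError(f"measurements mix strains: {sorted(strains)}")
    return strains.pop()


def _mean_ratio(ms: Sequence[ReporterMeasurement]) -> float:
    if not ms:
        raise ValueError("empty measurement set")
    return float(np.mean([fl_ratio(m) for m in ms]))


def _percent_of_control(
    test: Sequence[ReporterMeasurement],
    control: Sequence[ReporterMeasurement],
    paired: bool,
) -> tuple[float, float, int]:
    """percent, SEM over replicates, n. SEM is of per-replicate percentages
    (against the control mean when unpaired)."""
    if paired:
        if len(test) != len(control):
            raise ValueError("paired mode needs equally sized sets")
        t = sorted(test, key=lambda m: m.replicate_id)
        c = sorted(control, key=lambda m: m.replicate_id)
        per_rep = np.array([100.0 * fl_ratio(a) / fl_ratio(b) for a, b in zip(t, c)])
    else:
        denom = _mean_ratio(control)
        if denom == 0:
            raise ValueError("control ratio is zero")
        per_rep = np.array([100.0 * fl_ratio(m) / denom for m in test])
    value = float(per_rep.mean())
    sem = float(per_rep.std(ddof=1) / np.sqrt(per_rep.size)) if per_rep.size > 1 else float("nan")
    return value, sem, per_rep.size


def frameshift_efficiency(
    test: Sequence[ReporterMeasurement],
    control: Sequence[ReporterMeasurement],
    paired: bool = False,
) -> FidelityResult:
    """Programmed frameshifting efficiency (%): F/R of the PRF construct
    over F/R of the 0-frame control, x100, within one strain."""
    strain = _check_same_strain(test, control)
    value, sem, n = _percent_of_control(test, control, paired)
    return FidelityResult("fs_efficiency_pct", value, strain, n, sem)


def readthrough_percent(
    stop_samples: Sequence[ReporterMeasurement],
    sense_samples: Sequence[ReporterMeasurement],
    paired: bool = False,
) -> FidelityResult:
    """Stop-codon readthrough (%): F/R of the stop-codon reporter over F/R of
    the sense-codon reporter, x100 (theoretical maximum 100%)."""
    strain = _check_same_strain(stop_samples, sense_samples)
    value, sem, n = _percent_of_control(stop_samples, sense_samples, paired)
    return FidelityResult("readthrough_pct", value, strain, n, sem)


def ires_activity(
    ires_samples: Sequence[ReporterMeasurement],
    reference_strain_samples: Sequence[ReporterMeasurement],
) -> FidelityResult:
    """IRES activity (%): strain F/R normalized to the reference strain's F/R."""
    if not ires_samples or not reference_strain_samples:
        raise ValueError("empty measurement set")
    denom = _mean_ratio(reference_strain_samples)
    if denom == 0:
        raise ValueError("reference strain ratio is zero")
    per_rep = np.array([100.0 * fl_ratio(m) / denom for m in ires_samples])
    strain = _check_same_strain(ires_samples)
    sem = float(per_rep.std(ddof=1) / np.sqrt(per_rep.size)) if per_rep.size > 1 else float("nan")
    return FidelityResult("ires_activity_pct", float(per_rep.mean()), strain, per_rep.size, sem)


@dataclass
class FidelityComparison:
    fold: float
    p: float | None
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float


def fidelity_compare(
    replicates_a: Sequence[float],
    replicates_b: Sequence[float],
    equal_var: bool = True,
) -> FidelityComparison:
    """Fold change mean_b/mean_a with a two-tailed Student t-test.

    With fewer than 3 replicates in either set the p-value is withheld
    (a warning is issued) and only the fold change is reported.
    ``equal_var=False`` switches to Welch's t-test.
    """
    a = np.asarray(replicates_a, dtype=np.float64)
    b = np.asarray(replicates_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both replicate sets must be non-empty")
    fold = float(b.mean() / a.mean())
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    if a.size < 3 or b.size < 3:
        warnings.warn("fewer than 3 replicates: p-value withheld", stacklevel=2)
        p = None
    elif np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate zero-variance sets: identical means are indistinguishable,
        # different means are separated with certainty
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return FidelityComparison(
        fold=fold, p=p, mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=sem(a), sem_b=sem(b),
    )
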