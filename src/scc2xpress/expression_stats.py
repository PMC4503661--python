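"""Expression summaries: MA quantities, DE classification, enrichment, BH.

M is log2(condition / reference) of mean expression and A the geometric mean
of the two RPKM values; differential-expression calls are consumed from an
upstream table (this module summarizes, it never fits a count model).
Gene-set over-representation uses the upper-tail hypergeometric test and
p-values are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDOCOUNT = 0.5


class DeCounts(NamedTuple):
    n_up: int
    n_down: int
    n_total: int


def ma_transform(rpkm_ref, rpkm_cond, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """M = log2((cond+e)/(ref+e)); A = sqrt((cond+e)(ref+e)). Vectorized.

    The pseudocount e keeps zero-RPKM features finite; it must be > 0 when
    any input can be zero.
    """
    ref = np.asarray(rpkm_ref, dtype=np.float64) + pseudocount
    cond = np.asarray(rpkm_cond, dtype=np.float64) + pseudocount
    if np.any(ref <= 0) or np.any(cond <= 0):
        raise ValueError("RPKM + pseudocount must be positive")
    m = np.log2(cond / ref)
    a = np.sqrt(cond * ref)
    if m.ndim == 0:
        return float(m), float(a)
    return m, a


def fold_change_threshold(fc: float = 1.5) -> float:
    """Absolute log2 cutoff for a linear fold-change threshold.

    fold_change_threshold(1.5) = 0.585, conventionally displayed as 0.6.
    """
    if fc <= 0:
        raise ValueError("fold change must be > 0")
    return abs(float(np.log2(fc)))


def classify_de(
    points: pd.DataFrame,
    alpha: float = 0.05,
    log2_cutoff: float | None = None,
) -> DeCounts:
    """Count up/down/total DE features from columns ``adj_p`` and ``M``.

    A feature is differentially expressed when adj_p < alpha (and, when a
    cutoff is given, additionally |M| >= cutoff); direction is the sign of M.
    """
    for col in ("adj_p", "M"):
        if col not in points.columns:
            raise ValueError(f"missing column {col!r}")
    if points["adj_p"].isna().any():
        raise ValueError("adj_p contains missing values")
    de = points["adj_p"] < alpha
    if log2_cutoff is not None:
        de &= points["M"].abs() >= log2_cutoff
    n_up = int((de & (points["M"] > 0)).sum())
    n_down = int((de & (points["M"] < 0)).sum())
    return DeCounts(n_up=n_up, n_down=n_down, n_total=n_up + n_down)


def hypergeom_enrichment(
    population_n: int, annotated_k: int, selected_n: int, overlap_x: int
) -> float:
    """Upper-tail over-representation p-value: P[X >= x], X ~ HG(N, k, n)."""
    N, k, n, x = population_n, annotated_k, selected_n, overlap_x
    if not (0 <= x <= min(k, n) and k <= N and n <= N and x >= 0):
        raise ValueError(
            f"inconsistent hypergeometric arguments N={N}, k={k}, n={n}, x={x}"
        )
    return float(stats.hypergeom.sf(x - 1, N, k, n))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    population_n: int
    annotated_k: int
    selected_n: int
    overlap_x: int
    p: float
    adj_p: float


def enrich_terms(
    population: Sequence[str],
    selected: Sequence[str],
    term_to_genes: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Over-representation of each term's genes in the selected set.

    Annotated and overlap counts are restricted to the population; BH
    adjustment is applied across the terms of this call (one family).
    """
    pop = set(population)
    sel = set(selected) & pop
    if not sel:
        raise ValueError("selected set is empty after restriction to the population")
    rows = []
    for term, genes in term_to_genes.items():
        annotated = set(genes) & pop
        overlap = annotated & sel
        p = hypergeom_enrichment(len(pop), len(annotated), len(sel), len(overlap))
        rows.append(
            {
                "term_id": term,
                "population_n": len(pop),
                "annotated_k": len(annotated),
                "selected_n": len(sel),
                "overlap_x": len(overlap),
                "p": p,
            }
        )
    df = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    return df


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
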