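"""Percentage normalization and cross-species correlation of family sizes.

Counts are normalized per species as ``count / searched_total * 100`` where
the searched total is the number of primary-transcript proteins — this makes
repertoire sizes comparable across proteomes of very different sizes and
ploidy (a whole-genome duplication doubles both numerator and denominator).

The correlation analysis mirrors the published comparison: each receptor
column is correlated against %NB-ARC with a sample Pearson coefficient, a
two-sided t-test p-value (n-2 degrees of freedom) and Bonferroni adjustment
across the suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RepertoireTable",
    "CorrelationResult",
    "compute_percentages",
    "pearson_correlation",
    "bonferroni_adjust",
    "correlation_suite",
    "load_percentage_table",
]

#: Derived columns: name -> list of count columns summed before normalization.
DERIVED_COLUMNS = {
    "LRR-RLK-excl-XII": None,   # LRR-RLK minus subgroup XII (special-cased)
    "LRR-RLP+XII": ("LRR-RLP", "LRR-RLK-XII"),
}


class RepertoireTable:
    """Species x receptor-family table of counts, totals and percentages.

    Wraps two aligned DataFrames (``counts`` and ``percentages``, one row per
    species) plus the per-species searched totals and optional clade labels.
    Percentage cells are exactly ``count / total * 100``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        totals: pd.Series,
        clades: Optional[pd.Series] = None,
    ):
        if not (totals.loc[counts.index] > 0).all():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"non-positive searched totals for species: {bad}")
        self.counts = counts.astype(float)
        self.totals = totals.loc[counts.index].astype(float)
        self.percentages = self.counts.div(self.totals, axis=0) * 100.0
        if clades is None:
            clades = pd.Series("unknown", index=counts.index)
        self.clades = clades.loc[counts.index]

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def columns(self) -> list[str]:
        return list(self.counts.columns)

    def filter_clade(self, clade: Optional[str]) -> "RepertoireTable":
        if clade is None:
            return self
        keep = self.clades == clade
        return RepertoireTable(
            self.counts.loc[keep], self.totals.loc[keep], self.clades.loc[keep]
        )

    def percent(self, column: str) -> pd.Series:
        return self.percentages[column]

    def to_frame(self) -> pd.DataFrame:
        """Flat export: species, clade, searched total, then count/% pairs."""
        out = pd.DataFrame(
            {"species": self.counts.index, "clade": self.clades.values,
             "searched_total": self.totals.values}
        ).set_index("species")
        for col in self.counts.columns:
            out[f"n_{col}"] = self.counts[col]
            out[f"pct_{col}"] = self.percentages[col]
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def compute_percentages(
    counts: pd.DataFrame,
    totals: pd.Series,
    clades: Optional[pd.Series] = None,
    subgroup_counts: Optional[pd.DataFrame] = None,
) -> RepertoireTable:
    """Build a :class:`RepertoireTable`, adding derived columns.

    `counts` has one row per species and one column per family; optional
    `subgroup_counts` has one column per LRR-RLK subgroup (named
    ``LRR-RLK-<label>``).  Derived columns — ``LRR-RLK-excl-XII`` and
    ``LRR-RLP+XII`` — are computed as count sums *before* normalization.
    """
    counts = counts.copy()
    if subgroup_counts is not None:
        for col in subgroup_counts.columns:
            counts[col] = subgroup_counts[col]
    if "LRR-RLK" in counts and "LRR-RLK-XII" in counts:
        counts["LRR-RLK-excl-XII"] = counts["LRR-RLK"] - counts["LRR-RLK-XII"]
    if "LRR-RLP" in counts and "LRR-RLK-XII" in counts:
        counts["LRR-RLP+XII"] = counts["LRR-RLP"] + counts["LRR-RLK-XII"]
    return RepertoireTable(counts, totals, clades)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one receptor column against the reference."""

    pair: str
    r: float
    p: float
    p_adjusted: float
    n: int

    def __post_init__(self):
        if not -1.0000000001 <= self.r <= 1.0000000001:
            raise ValueError(f"correlation out of range: {self.r}")


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], pair: str = ""
) -> CorrelationResult:
    """Sample Pearson r with a two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = scipy.stats.pearsonr(x, y)
    return CorrelationResult(
        pair=pair, r=float(res.statistic), p=float(res.pvalue),
        p_adjusted=float(res.pvalue), n=n,
    )


def bonferroni_adjust(pvals: Sequence[float]) -> list[float]:
    """Bonferroni family-wise correction: ``min(1, p * k)``."""
    pvals = list(pvals)
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    if not pvals:
        return []
    return list(multipletests(pvals, method="bonferroni")[1])


def format_pvalue(p: float) -> str:
    """Textual p-value; below double precision prints as '< 1e-300'."""
    if p == 0:
        return "< 1e-300"
    return f"{p:.3g}"


def correlation_suite(
    table: RepertoireTable,
    clade: Optional[str] = None,
    reference: str = "NB-ARC",
    columns: Optional[Iterable[str]] = None,
    drop_zero_species: bool = False,
) -> list[CorrelationResult]:
    """Correlate every receptor column against %`reference`.

    Bonferroni adjustment is applied across the executed suite (k = number of
    tests run).  `drop_zero_species` excludes, per pair, species where either
    percentage is zero (no receptor identified — the grey "null" cells).
    Results are returned in column order; row order of the table is
    irrelevant.
    """
    sub = table.filter_clade(clade)
    if columns is None:
        columns = [c for c in sub.columns if c != reference]
    ref = sub.percent(reference)
    raw: list[CorrelationResult] = []
    for col in columns:
        x = sub.percent(col)
        y = ref
        if drop_zero_species:
            keep = (x > 0) & (y > 0)
            x, y = x[keep], y[keep]
        raw.append(pearson_correlation(x.values, y.values,
                                       pair=f"{col} vs {reference}"))
    adj = bonferroni_adjust([r.p for r in raw])
    return [
        CorrelationResult(r.pair, r.r, r.p, a, r.n)
        for r, a in zip(raw, adj)
    ]


def summarize_correlations(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Tabular summary of a correlation suite (one row per pair)."""
    return pd.DataFrame(
        {
            "pair": [r.pair for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "p_bonferroni": [r.p_adjusted for r in results],
            "n": [r.n for r in results],
        }
    )


def load_percentage_table(path) -> RepertoireTable:
    """Load a published-style percentage table from CSV.

    Expected schema: a ``species`` column, optional ``clade`` and
    ``searched_total`` columns, and either ``n_<family>`` count columns or
    ``pct_<family>`` percentage columns (as written by
    :meth:`RepertoireTable.to_csv`).  When only percentages are present the
    totals default to 100 so counts equal percentages — correlations are
    unchanged by that convention.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("percentage table needs a 'species' column")
    df = df.set_index("species")
    clades = df["clade"] if "clade" in df else None
    n_cols = [c for c in df.columns if c.startswith("n_")]
    pct_cols = [c for c in df.columns if c.startswith("pct_")]
    if "searched_total" in df and n_cols:
        counts = df[n_cols].rename(columns=lambda c: c[2:])
        totals = df["searched_total"]
    elif pct_cols:
        counts = df[pct_cols].rename(columns=lambda c: c[4:])
        totals = pd.Series(100.0, index=df.index)
    else:
        raise ValueError("no n_<family> or pct_<family> columns found")
    return RepertoireTable(counts, totals, clades)
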