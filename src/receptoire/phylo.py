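"""Phylogeny-aware correlation of receptor repertoires.

Per-species receptor percentages are converted to pairwise distance matrices
(absolute difference), the species tree to a patristic distance matrix, and
matrix pairs are compared with Mantel permutation tests.  The partial Mantel
test correlates two receptor-distance matrices while controlling for
phylogenetic distance, so shared ancestry alone cannot explain an
association.  Empirical p-values use the add-one rule
``(1 + #{permuted r >= observed}) / (n_perm + 1)`` with a one-sided
(greater) alternative by default, matching the R vegan convention; the
default permutation count is 10,000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "percent_to_distance",
    "mantel",
    "partial_mantel",
    "fdr_adjust",
]

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with a provenance tag."""

    labels: list
    values: np.ndarray
    tag: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("matrix not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > _SYM_TOL:
            raise ValueError("nonzero diagonal")
        if (self.values < -_SYM_TOL).any():
            raise ValueError("negative distances")

    def __len__(self):
        return len(self.labels)

    def restrict(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Sub-matrix restricted and reordered to `labels`."""
        index = {lb: i for i, lb in enumerate(self.labels)}
        missing = [lb for lb in labels if lb not in index]
        if missing:
            raise KeyError(f"labels absent from matrix: {missing}")
        idx = np.array([index[lb] for lb in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.tag)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (row-major, excluding the diagonal)."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]


def percent_to_distance(
    values: Sequence[float], labels: Sequence[str], tag: str = ""
) -> DistanceMatrix:
    """Distance matrix of absolute percentage differences |x_i - x_j|."""
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite percentage values")
    mat = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(list(labels), mat, tag)


@dataclass(frozen=True)
class MantelResult:
    """Mantel (or partial Mantel) statistic with its permutation p-value."""

    pair: str
    r: float
    n_perm: int
    p: float
    p_adjusted: Optional[float] = None
    seed: Optional[int] = None
    alternative: str = "greater"


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    if denom == 0:
        raise ValueError("zero variance in distance entries")
    return float((u @ v) / denom)


def _check_labels(*mats: DistanceMatrix) -> None:
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            raise ValueError(
                "distance matrices carry different labels or label order"
            )


#: tolerance for tie handling: permuted statistics equal to the observed one
#: up to floating-point noise count as "at least as extreme" (required for a
#: valid permutation test; correlations are bounded by 1 so an absolute
#: tolerance suffices)
_TIE_EPS = 1e-9


def _perm_pvalue(observed: float, permuted: np.ndarray, alternative: str) -> float:
    n = permuted.size
    if alternative == "greater":
        count = int(np.sum(permuted >= observed - _TIE_EPS))
    elif alternative == "less":
        count = int(np.sum(permuted <= observed + _TIE_EPS))
    elif alternative == "two-sided":
        count = int(np.sum(np.abs(permuted) >= abs(observed) - _TIE_EPS))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + count) / (n + 1)


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson correlation of the upper-triangle entries;
    the null distribution is obtained by simultaneously permuting rows and
    columns of B.
    """
    _check_labels(A, B)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(A)
    a = A.condensed()
    iu = np.triu_indices(n, k=1)
    observed = _pearson(a, B.condensed())
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        bp = B.values[np.ix_(perm, perm)]
        permuted[k] = _pearson(a, bp[iu])
    p = _perm_pvalue(observed, permuted, alternative)
    return MantelResult(
        pair=f"{A.tag}~{B.tag}", r=observed, n_perm=n_perm, p=p,
        seed=seed, alternative=alternative,
    )


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    denom = (1 - rac**2) * (1 - rbc**2)
    if denom <= 0:
        raise ValueError(
            "degenerate control matrix: |correlation| = 1 with a test matrix"
        )
    return (rab - rac * rbc) / np.sqrt(denom)


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel test of A ~ B controlling for C.

    The statistic is the first-order partial correlation of the condensed
    matrices, ``(r_AB - r_AC r_BC) / sqrt((1-r_AC^2)(1-r_BC^2))``; the null
    permutes A's rows/columns and recomputes the partial statistic (r_BC is
    unaffected by the permutation and stays fixed).
    """
    _check_labels(A, B, C)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(A)
    iu = np.triu_indices(n, k=1)
    a, b, c = A.condensed(), B.condensed(), C.condensed()
    rbc = _pearson(b, c)
    observed = _partial_r(_pearson(a, b), _pearson(a, c), rbc)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        ap = A.values[np.ix_(perm, perm)][iu]
        permuted[k] = _partial_r(_pearson(ap, b), _pearson(ap, c), rbc)
    p = _perm_pvalue(observed, permuted, alternative)
    return MantelResult(
        pair=f"{A.tag}~{B.tag}|{C.tag}", r=observed, n_perm=n_perm, p=p,
        seed=seed, alternative=alternative,
    )


def fdr_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = list(pvals)
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    if not pvals:
        return []
    return list(multipletests(pvals, method="fdr_bh")[1])
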