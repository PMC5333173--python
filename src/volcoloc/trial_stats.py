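"""Contingency-table statistics for subjective-rating comparisons.

Provides 5-to-3 rating grouping, the cell-wise Yates-corrected chi-square
statistic, Cramér's V effect size V = sqrt(chi2 / (N (k - 1))), and the
chi-square upper-tail p-value.

The Yates continuity correction is applied per cell for any table size (with
the per-cell term floored at zero when |O - E| < 0.5), not only at one degree
of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RatingTable:
    """Non-negative counts: rows = interfaces, columns = rating levels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        """The lesser of the row and column counts."""
        return min(self.counts.shape)

    @property
    def df(self) -> int:
        rows, cols = self.counts.shape
        return (rows - 1) * (cols - 1)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    v: float


def group_ratings(raw) -> np.ndarray:
    """Collapse 5-point rating counts to 3 levels: {1, 2, 3} pooled, 4 and 5 kept.

    Accepts a 1-D vector of 5 counts or a table whose last axis has 5 levels;
    totals are preserved.
    """
    raw = np.asarray(raw)
    if raw.shape[-1] != 5:
        raise ValueError(f"expected 5 rating levels on the last axis, got {raw.shape[-1]}")
    pooled = raw[..., :3].sum(axis=-1, keepdims=True)
    return np.concatenate([pooled, raw[..., 3:]], axis=-1)


def chi2_yates(table: RatingTable | np.ndarray) -> tuple[float, int]:
    """Cell-wise Yates-corrected chi-square statistic and degrees of freedom.

    chi2 = sum over cells of (max(|O - E| - 0.5, 0))^2 / E with expected counts
    from the row/column marginals.  A zero marginal makes the table degenerate.
    """
    if not isinstance(table, RatingTable):
        table = RatingTable(table)
    counts = table.counts.astype(np.float64)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    if total == 0 or np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate table: a marginal total is zero")
    expected = row @ col / total
    corrected = np.maximum(np.abs(counts - expected) - 0.5, 0.0)
    chi2 = float((corrected ** 2 / expected).sum())
    return chi2, table.df


def chi2_uncorrected(table: RatingTable | np.ndarray) -> tuple[float, int]:
    """Plain Pearson chi-square (no continuity correction), same contract."""
    if not isinstance(table, RatingTable):
        table = RatingTable(table)
    counts = table.counts.astype(np.float64)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    if total == 0 or np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate table: a marginal total is zero")
    expected = row @ col / total
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, table.df


def cramers_v(chi2: float, n_total: int, k: int) -> float:
    """Cramér's V = sqrt(chi2 / (N (k - 1))), clipped to [0, 1].

    ``k`` is the lesser of the table's row and column counts; ``N`` the sample
    size of the analyzed table.
    """
    if n_total <= 0:
        raise ValueError("N must be positive")
    if k < 2:
        raise ValueError("k must be >= 2 for a meaningful association measure")
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    return min(1.0, math.sqrt(chi2 / (n_total * (k - 1))))


def chi2_pvalue(chi2: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    return float(stats.chi2.sf(chi2, df))


def analyze_table(table: RatingTable | np.ndarray) -> ChiSquareResult:
    """Yates chi-square, p-value and Cramér's V for one contingency table."""
    if not isinstance(table, RatingTable):
        table = RatingTable(table)
    chi2, df = chi2_yates(table)
    return ChiSquareResult(
        chi2=chi2,
        df=df,
        p=chi2_pvalue(chi2, df),
        v=cramers_v(chi2, table.n_total, table.k),
    )
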