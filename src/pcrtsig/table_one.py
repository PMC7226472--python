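"""Cohort-comparability testing: chi-square and Fisher's exact over Table-1-style
contingency tables of clinicopathological categories by cohort.

Policy: 2x2 chi-square uses the Yates continuity correction; Fisher's exact
is the two-sided sum of hypergeometric probabilities no larger than the
observed table's (full enumeration for r x c tables).  In ``auto`` mode
Fisher is used whenever any expected cell count is below 5, the classical
rule of thumb.  Category levels with zero count in every cohort are dropped
before testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import STAGE_VOCABULARY, SampleAnnotation

__all__ = ["ContingencyTable", "compare_cohorts", "build_table1"]

_ENUM_BUDGET = 2_000_000  # max tables enumerated by the r x c exact test


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of category levels (columns) per cohort (rows)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.counts)
        if a.ndim != 2 or a.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape inconsistent with labels")
        if np.any(a < 0) or not np.issubdtype(a.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def _drop_zero(a: np.ndarray) -> np.ndarray:
    a = a[:, a.sum(axis=0) > 0]
    return a[a.sum(axis=1) > 0, :]


def _log_factorials(n: int) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])


def _fisher_rxc(a: np.ndarray) -> float:
    """Two-sided Fisher exact p for an r x c table by full enumeration.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one (with a
    small relative tolerance against floating-point ties).
    """
    rows = a.sum(axis=1)
    cols = a.sum(axis=0)
    n = int(a.sum())
    lf = _log_factorials(n)
    log_const = lf[rows].sum() + lf[cols].sum() - lf[n]

    def log_p(table: np.ndarray) -> float:
        return log_const - lf[table].sum()

    lp_obs = log_p(a)
    r, c = a.shape
    total = 0.0
    count = 0

    # recursive enumeration over rows; the last row is forced by the margins
    def rec(i: int, remaining_cols: np.ndarray, acc: list[np.ndarray]) -> None:
        nonlocal total, count
        if i == r - 1:
            last = remaining_cols
            if np.any(last < 0):
                return
            count += 1
            if count > _ENUM_BUDGET:
                raise ValueError("r x c exact test exceeds the enumeration budget")
            table = np.vstack(acc + [last])
            lp = log_p(table)
            if lp <= lp_obs + 1e-9:
                total += math.exp(lp)
            return
        # enumerate row i cell by cell
        def cells(j: int, left_in_row: int, row: list[int]) -> None:
            if j == c - 1:
                if left_in_row <= remaining_cols[j]:
                    rec(i + 1,
                        remaining_cols - np.array(row + [left_in_row]),
                        acc + [np.array(row + [left_in_row])])
                return
            for v in range(min(left_in_row, remaining_cols[j]) + 1):
                cells(j + 1, left_in_row - v, row + [v])

        cells(0, int(rows[i]), [])

    rec(0, cols.copy(), [])
    return min(total, 1.0)


def compare_cohorts(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    method: str = "auto",
) -> tuple[float, str]:
    """p-value for independence of cohort and category.

    ``method``: ``chi2`` (Pearson; Yates-corrected for 2x2), ``fisher``
    (exact two-sided), or ``auto`` (Fisher when any expected cell < 5).
    Returns ``(p_value, method_used)``.  Degenerate tables (a single nonzero
    row or column after dropping empty levels) give p = 1 with a warning.
    """
    a = table.to_array() if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    if np.any(a < 0):
        raise ValueError("counts must be non-negative")
    a = _drop_zero(a)
    if a.shape[0] < 2 or a.shape[1] < 2:
        warnings.warn("degenerate contingency table; p = 1", stacklevel=2)
        return 1.0, "degenerate"

    if method == "auto":
        expected = np.outer(a.sum(axis=1), a.sum(axis=0)) / a.sum()
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "chi2":
        correction = a.shape == (2, 2)
        p = float(stats.chi2_contingency(a, correction=correction)[1])
        return p, "chi2_yates" if correction else "chi2"
    if method == "fisher":
        if a.shape == (2, 2):
            p = float(stats.fisher_exact(a, alternative="two-sided")[1])
        else:
            p = _fisher_rxc(a)
        return p, "fisher"
    raise ValueError(f"unknown method {method!r}")


_TABLE1_VARIABLES = [
    "gender", "differentiation", "clin_T", "clin_N", "clin_M",
    "path_T", "path_N", "path_M",
]


def build_table1(
    annotations: Sequence[SampleAnnotation], method: str = "auto"
) -> pd.DataFrame:
    """Table-1-shaped comparison of training vs validation cohorts.

    One row per (variable, level) with counts and within-cohort percentages,
    plus the variable-level p-value and the test used.
    """
    df = pd.DataFrame(
        {
            "cohort": [a.cohort for a in annotations],
            **{v: [getattr(a, v) for a in annotations] for v in _TABLE1_VARIABLES},
        }
    )
    n_by_cohort = df["cohort"].value_counts()
    rows = []
    for var in _TABLE1_VARIABLES:
        levels = [lv for lv in STAGE_VOCABULARY[var]]
        counts = np.array(
            [
                [int(((df["cohort"] == coh) & (df[var] == lv)).sum()) for lv in levels]
                for coh in ("training", "validation")
            ],
            dtype=np.int64,
        )
        p, used = compare_cohorts(counts, method=method)
        for j, lv in enumerate(levels):
            rows.append(
                {
                    "variable": var,
                    "level": lv,
                    "training_n": counts[0, j],
                    "training_pct": 100.0 * counts[0, j] / n_by_cohort.get("training", 1),
                    "validation_n": counts[1, j],
                    "validation_pct": 100.0 * counts[1, j] / n_by_cohort.get("validation", 1),
                    "p_value": p,
                    "method": used,
                }
            )
    return pd.DataFrame(rows)
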