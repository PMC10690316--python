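"""Descriptive cohort tables and the two-group tests behind them.

Builds "Table 1"-style summaries of a two-group cohort: counts (percent)
with chi-square or Fisher's exact test for categorical variables,
mean (SD) with the pooled t-test for normally distributed continuous
variables, and median (IQR) with the Mann-Whitney U test otherwise.
Percent formatting rounds half away from zero to one decimal, matching
clinical-table convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "percent",
    "chi_square_2x2",
    "fisher_exact",
    "two_group_continuous",
    "build_cohort_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts (a, b) = group-1 exposed/unexposed, (c, d) = group-2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def expected(self) -> np.ndarray:
        t = self.as_array()
        return np.outer(t.sum(1), t.sum(0)) / t.sum()


def percent(count: int, denom: int) -> float:
    """100·count/denom rounded half-away-from-zero to one decimal."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denom:
        raise ValueError("count must lie in [0, denom]")
    x = Decimal(100 * count) / Decimal(denom)
    return float(x.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def chi_square_2x2(t: ContingencyTable2x2, continuity: bool = True
                   ) -> tuple[float, float]:
    """Pearson chi-square (df=1) with optional Yates continuity correction."""
    arr = t.as_array()
    if (arr.sum(0) == 0).any() or (arr.sum(1) == 0).any():
        raise ValueError("zero margin in contingency table")
    if (t.expected() <= 0).any():
        raise ValueError("expected counts must be positive")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=continuity)
    return float(stat), float(p)


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (probability-mass summation rule)."""
    _, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return float(p)


def two_group_continuous(x, y, normal: bool = True, welch: bool = False
                         ) -> tuple[float, float]:
    """Two-sided two-group test for continuous data.

    ``normal=True`` → independent t-test (pooled variance unless ``welch``);
    otherwise Mann-Whitney U with normal approximation and tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values")
    if normal:
        if np.concatenate([x, y]).std() == 0:
            raise ValueError("zero combined variance")
        stat, p = stats.ttest_ind(x, y, equal_var=not welch)
    else:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
    return float(stat), float(p)


_VALID_TYPES = {"categorical", "normal", "nonnormal"}
_EXPECTED_MIN = 5  # Fisher substituted below this expected cell count


def _categorical_row(var, x1, x2, n1, n2):
    a, c = int(x1.sum()), int(x2.sum())
    table = ContingencyTable2x2(a, n1 - a, c, n2 - c)
    if (table.expected() < _EXPECTED_MIN).any():
        p = fisher_exact(table)
        test = "fisher"
        logger.info("variable %s: expected cell < %d, using Fisher", var,
                    _EXPECTED_MIN)
    else:
        _, p = chi_square_2x2(table)
        test = "chi-square"
    return {
        "variable": var, "type": "categorical",
        "group1": f"{a} ({percent(a, n1):.1f})",
        "group2": f"{c} ({percent(c, n2):.1f})",
        "test": test, "p": p,
    }


def _continuous_row(var, x1, x2, normal):
    if normal:
        _, p = two_group_continuous(x1, x2, normal=True)
        fmt = lambda v: f"{v.mean():.1f} ({v.std(ddof=1):.1f})"
        test = "t-test"
    else:
        _, p = two_group_continuous(x1, x2, normal=False)
        fmt = lambda v: (f"{np.median(v):.1f} "
                         f"({np.percentile(v, 25):.1f}-{np.percentile(v, 75):.1f})")
        test = "mann-whitney"
    return {
        "variable": var, "type": "normal" if normal else "nonnormal",
        "group1": fmt(np.asarray(x1, float)), "group2": fmt(np.asarray(x2, float)),
        "test": test, "p": p,
    }


def build_cohort_table(data: pd.DataFrame, group: str,
                       schema: dict[str, str]) -> pd.DataFrame:
    """Two-group descriptive table with per-row tests.

    ``schema`` maps variable name → ``categorical`` / ``normal`` /
    ``nonnormal``; ``group`` names the binary 0/1 grouping column.
    """
    g = data[group].astype(int)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError("group column must have exactly two levels")
    m1, m2 = g == levels[1], g == levels[0]  # group1 = positive class
    n1, n2 = int(m1.sum()), int(m2.sum())
    rows = []
    for var, kind in schema.items():
        if kind not in _VALID_TYPES:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        x1, x2 = data.loc[m1, var], data.loc[m2, var]
        if kind == "categorical":
            rows.append(_categorical_row(var, x1.astype(int), x2.astype(int),
                                         n1, n2))
        else:
            rows.append(_continuous_row(var, x1, x2, kind == "normal"))
    out = pd.DataFrame(rows)
    out.attrs["n_group1"] = n1
    out.attrs["n_group2"] = n2
    return out
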