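"""Pairwise Pearson correlation of facility-level indicators.

Facilities are the observational units. Each pair of indicators is
correlated over the facilities where *both* are defined (pairwise
deletion), so the per-cell sample size n varies with missingness. The
two-sided p-value comes from the t transform with n - 2 degrees of
freedom. p-values are reported raw (no multiple-testing adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationCell:
    indicator_a: str
    indicator_b: str
    r: float
    p_value: float
    n: int


def pearson(x, y) -> tuple[float, float, int]:
    """Product-moment correlation with pairwise deletion.

    Returns ``(r, p_value, n)`` where n counts the pairs with both values
    present. With n = 2 the correlation is +/-1 by construction and the
    p-value is undefined (NaN); with n < 2, or zero variance in either
    vector, the whole cell is undefined.
    """
    x = np.asarray(pd.Series(x), dtype=float)
    y = np.asarray(pd.Series(y), dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    if n == 2:
        r = 1.0 if (x[1] - x[0]) * (y[1] - y[0]) > 0 else -1.0
        return r, np.nan, n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def correlation_matrix(indicator_table: pd.DataFrame,
                       indicator_columns: list[str] | None = None
                       ) -> pd.DataFrame:
    """Long-format correlation table over all indicator pairs.

    Emits the upper triangle (``indicator_a`` before ``indicator_b`` in
    column order) including the unit diagonal; indicators that are missing
    for every facility are dropped with a log note.
    """
    if indicator_columns is None:
        indicator_columns = [c for c in indicator_table.columns
                             if c.startswith(("pct_", "mean_"))]
    cols = []
    for c in indicator_columns:
        if indicator_table[c].notna().sum() == 0:
            logger.warning("correlation: indicator %s entirely missing; dropped", c)
        else:
            cols.append(c)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            if a == b:
                n = int(indicator_table[a].notna().sum())
                rows.append({"indicator_a": a, "indicator_b": b,
                             "r": 1.0, "p_value": np.nan, "n": n})
                continue
            r, p, n = pearson(indicator_table[a], indicator_table[b])
            rows.append({"indicator_a": a, "indicator_b": b,
                         "r": r, "p_value": p, "n": n})
    return pd.DataFrame(rows, columns=["indicator_a", "indicator_b",
                                       "r", "p_value", "n"])


def correlation_square(long_table: pd.DataFrame, field: str = "r") -> pd.DataFrame:
    """Symmetric square matrix (DataFrame) from the long-format table."""
    names = list(dict.fromkeys(
        long_table["indicator_a"].tolist() + long_table["indicator_b"].tolist()))
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for row in long_table.itertuples(index=False):
        val = getattr(row, field)
        mat.loc[row.indicator_a, row.indicator_b] = val
        mat.loc[row.indicator_b, row.indicator_a] = val
    return mat
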