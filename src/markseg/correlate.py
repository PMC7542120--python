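"""Tie-adjusted Spearman correlation over segment-table attributes.

Segment attributes are heavily tied (0/1 indicators, small integer codes,
many exact-zero coverages), so the rank correlation must use midranks:
every group of tied values receives the average of the ranks it spans,
and the coefficient is the Pearson product-moment correlation of those
midranks.  On tie-free data this reduces to the classical
``1 - 6 * sum(d^2) / (n * (n^2 - 1))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["CorrelationMatrix", "spearman_ties", "correlation_matrix"]


def spearman_ties(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation adjusted for ties.

    Rows with a missing value in either vector are dropped pairwise.
    Returns NaN (with a warning) when fewer than two complete pairs
    remain or either vector is constant after dropping.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2:
        warnings.warn("fewer than 2 complete pairs; correlation undefined")
        return float("nan")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector; correlation undefined")
        return float("nan")
    rx = rankdata(x)  # midranks: ties get the average rank
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


@dataclass
class CorrelationMatrix:
    """All-pairs tie-adjusted Spearman correlations with pairwise n."""

    labels: list[str]
    rho: np.ndarray  # symmetric, NaN marks undefined entries
    n: np.ndarray  # complete pairs used per entry

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.labels, columns=self.labels)


def correlation_matrix(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Tie-adjusted Spearman correlation between every pair of attributes.

    ``columns`` selects and orders the attributes (default: all numeric
    columns except the coordinate bookkeeping ones); order is preserved
    so related attributes can be displayed as blocks.  Missing values are
    dropped pairwise, not listwise, since annotations may be partially
    available.
    """
    if columns is None:
        skip = {"segment_id", "chrom", "start", "end"}
        columns = [
            c
            for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        ]
    columns = list(columns)
    for c in columns:
        if c not in table.columns:
            raise ValueError(f"unknown column {c!r}")
    if len(columns) < 2:
        raise ValueError("need at least 2 columns to correlate")

    k = len(columns)
    rho = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=np.int64)
    data = [table[c].to_numpy(dtype=float) for c in columns]
    for i in range(k):
        for j in range(i, k):
            keep = ~(np.isnan(data[i]) | np.isnan(data[j]))
            n[i, j] = n[j, i] = int(keep.sum())
            if i == j:
                if n[i, i] >= 2 and not np.all(data[i][keep] == data[i][keep][0]):
                    rho[i, i] = 1.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = spearman_ties(data[i], data[j])
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(labels=columns, rho=rho, n=n)
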