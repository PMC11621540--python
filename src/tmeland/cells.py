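"""Segmented-cell marker-intensity preprocessing.

Prepares multiplexed-immunostaining cell tables for clustering: cells
whose total signal intensity falls at or beyond the 1st/99th percentile
of totals are removed as segmentation outliers, and marker intensities
are normalized with a centered log-ratio transform taken per marker
across cells (log1p so zero intensities stay defined).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

NON_MARKER_COLUMNS = ("x", "y", "total")


class CellTableError(ValueError):
    pass


def marker_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in NON_MARKER_COLUMNS]


def filter_outlier_cells(
    table: pd.DataFrame,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
) -> tuple[pd.DataFrame, pd.Index]:
    """Remove cells with outlying total intensity.

    A cell is dropped when the sum of its marker intensities is >= the
    ``high_pct`` percentile or <= the ``low_pct`` percentile of all cells'
    totals.  Percentiles use linear interpolation.  If the two percentiles
    coincide (e.g. all totals equal) filtering is skipped with a warning.

    Returns (filtered table, index of removed cells).  Requires >= 10
    cells — the percentile filter is undefined at tiny n.
    """
    if len(table) < 10:
        raise CellTableError(f"need >= 10 cells, got {len(table)}")
    totals = table[marker_columns(table)].sum(axis=1)
    lo = np.percentile(totals, low_pct)
    hi = np.percentile(totals, high_pct)
    if lo == hi:
        warnings.warn(
            "degenerate total-intensity percentiles; outlier filter skipped",
            stacklevel=2,
        )
        return table.copy(), table.index[:0]
    removed = table.index[(totals >= hi) | (totals <= lo)]
    return table.drop(index=removed), removed


def clr_normalize(table: pd.DataFrame, margin: int = 2) -> pd.DataFrame:
    """Centered log-ratio normalization of marker intensities.

    ``margin=2`` (default, the across-cells convention): per marker,
    y = log1p(x) − mean over cells of log1p(x), so every marker column
    centers to 0.  ``margin=1`` centers per cell across markers instead.
    Non-marker columns (centroids, totals) pass through unchanged.
    """
    if margin not in (1, 2):
        raise CellTableError("margin must be 1 (within cell) or 2 (across cells)")
    cols = marker_columns(table)
    x = table[cols].to_numpy(dtype=float)
    if np.any(x < 0):
        raise CellTableError("intensities must be non-negative")
    logged = np.log1p(x)
    axis = 0 if margin == 2 else 1
    centered = logged - logged.mean(axis=axis, keepdims=True)
    out = table.copy()
    out[cols] = centered
    return out
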