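"""Count normalization shared by the scoring and region modules."""

from __future__ import annotations

import numpy as np
import pandas as pd


def median_library_log2(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each spot to the median library size, then log2(x + 1).

    The normalization used upstream of PAGE scoring.  Zero-library spots
    are left as zeros.
    """
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    target = np.median(lib[lib > 0]) if np.any(lib > 0) else 1.0
    scale = np.divide(target, lib, out=np.zeros_like(lib), where=lib > 0)
    return np.log2(counts.mul(scale, axis=0) + 1.0)


def log_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalization: ln(1 + x * scale / library size).

    Spots with zero library size are normalized to all-zero rows.
    """
    arr = counts.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    lib = arr.sum(axis=1)
    fac = np.divide(scale, lib, out=np.zeros_like(lib), where=lib > 0)
    return pd.DataFrame(
        np.log1p(arr * fac[:, None]), index=counts.index, columns=counts.columns
    )
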