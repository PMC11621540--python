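"""Hexagonal spot lattice: the Visium array-coordinate convention.

Spots sit on a hex lattice addressed by integer ``(array_row, array_col)``
where row and column always share parity (row + col is even).  The six
nearest neighbors of ``(r, c)`` are ``(r, c ± 2)`` and ``(r ± 1, c ± 1)``.
Pixel coordinates use the raster convention: origin top-left, ``pixel_y``
increasing downward.  One unit of hex graph distance corresponds to one
spot pitch (center-to-center distance, 100 µm on the physical array).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPOT_PITCH_UM = 100.0  # center-to-center distance of neighboring spots
SPOT_DIAMETER_UM = 55.0

_REQUIRED_COLUMNS = ("array_row", "array_col", "pixel_x", "pixel_y", "in_tissue")


class GridError(ValueError):
    """Raised when spot-table content violates the lattice invariants."""


@dataclass
class SpotGrid:
    """Spot identities with hex array coordinates and pixel positions.

    Parameters
    ----------
    table
        DataFrame indexed by spot barcode with columns ``array_row``,
        ``array_col`` (shared parity), ``pixel_x``, ``pixel_y`` (full-res
        image pixels), ``in_tissue`` (bool) and optionally ``cluster``.
    pitch_px
        Spot pitch in pixels of the full-resolution image; used as the
        length unit for corridor widths and spot radii.
    """

    table: pd.DataFrame
    pitch_px: float = 100.0

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise GridError(f"spot table missing columns: {missing}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise GridError(f"duplicate spot barcodes: {dups[:5]}")
        parity = (t["array_row"].to_numpy() + t["array_col"].to_numpy()) % 2
        if np.any(parity != 0):
            bad = t.index[parity != 0].tolist()
            raise GridError(
                f"array_row + array_col must be even (hex parity); offending spots: {bad[:5]}"
            )
        px = t[["pixel_x", "pixel_y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(px)):
            raise GridError("non-finite pixel coordinates")
        if not (self.pitch_px > 0):
            raise GridError("pitch_px must be positive")

    @property
    def n_spots(self) -> int:
        return len(self.table)

    @property
    def spot_ids(self) -> pd.Index:
        return self.table.index

    @property
    def positions_px(self) -> np.ndarray:
        """(n_spots, 2) array of (pixel_x, pixel_y)."""
        return self.table[["pixel_x", "pixel_y"]].to_numpy(dtype=float)

    @property
    def array_coords(self) -> np.ndarray:
        """(n_spots, 2) integer array of (array_row, array_col)."""
        return self.table[["array_row", "array_col"]].to_numpy(dtype=int)

    @property
    def clusters(self) -> pd.Series:
        if "cluster" not in self.table.columns:
            raise GridError("spot table carries no cluster labels")
        return self.table["cluster"]

    def with_clusters(self, labels: pd.Series | dict) -> "SpotGrid":
        t = self.table.copy()
        t["cluster"] = pd.Series(labels).reindex(t.index)
        return SpotGrid(t, self.pitch_px)

    def hex_distance_matrix(self) -> np.ndarray:
        """All-pairs hex graph distance (n_spots × n_spots)."""
        rc = self.array_coords
        return hex_distance(
            rc[:, None, 0], rc[:, None, 1], rc[None, :, 0], rc[None, :, 1]
        )

    def adjacency_pairs(self) -> np.ndarray:
        """(k, 2) index pairs of spots at hex distance exactly 1."""
        index = {(r, c): i for i, (r, c) in enumerate(map(tuple, self.array_coords))}
        pairs = []
        for i, (r, c) in enumerate(map(tuple, self.array_coords)):
            for dr, dc in ((0, 2), (1, 1), (1, -1)):  # half the ring; avoids doubles
                j = index.get((r + dr, c + dc))
                if j is not None:
                    pairs.append((i, j))
        return np.asarray(pairs, dtype=int).reshape(-1, 2)


def hex_distance(r1, c1, r2, c2):
    """Graph distance on the shared-parity hex lattice.

    Uses cube coordinates ``x = (c - r) / 2``, ``z = r``, ``y = -x - z``;
    the distance is ``(|dx| + |dy| + |dz|) / 2``.  Accepts scalars or
    broadcastable integer arrays.
    """
    r1 = np.asarray(r1, dtype=np.int64)
    c1 = np.asarray(c1, dtype=np.int64)
    r2 = np.asarray(r2, dtype=np.int64)
    c2 = np.asarray(c2, dtype=np.int64)
    # (c - r) is even by the parity invariant; integer division is exact
    dx = (c2 - r2) // 2 - (c1 - r1) // 2
    dz = r2 - r1
    dy = -dx - dz
    return (np.abs(dx) + np.abs(dy) + np.abs(dz)) // 2


def ring_offsets(ring: int) -> list[tuple[int, int]]:
    """(dr, dc) offsets of all lattice sites at hex distance exactly `ring`."""
    if ring < 0:
        raise ValueError("ring must be non-negative")
    if ring == 0:
        return [(0, 0)]
    offsets = []
    for dr in range(-ring, ring + 1):
        for dc in range(-2 * ring, 2 * ring + 1):
            if (dr + dc) % 2 == 0 and hex_distance(0, 0, dr, dc) == ring:
                offsets.append((dr, dc))
    return offsets


def lattice_pixel_coords(
    array_row: np.ndarray, array_col: np.ndarray, pitch_px: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Map array coordinates to pixel centers of a regular hex lattice.

    ``pixel_x = array_col * pitch / 2`` and ``pixel_y = array_row *
    pitch * sqrt(3) / 2`` so that every hex-distance-1 pair is exactly one
    pitch apart in pixels.
    """
    x = np.asarray(array_col, dtype=float) * pitch_px / 2.0
    y = np.asarray(array_row, dtype=float) * pitch_px * np.sqrt(3.0) / 2.0
    return x, y


def full_lattice(n_rows: int, n_cols: int, pitch_px: float = 100.0) -> pd.DataFrame:
    """Spot table for a full n_rows × n_cols hex lattice.

    Column index j in row r maps to ``array_col = 2 j + (r mod 2)`` so the
    parity invariant holds everywhere.  Barcodes are synthetic
    ``SPOT-<row>-<col>`` strings.
    """
    if n_rows < 1 or n_cols < 1:
        raise GridError("lattice extent must be positive")
    rows = np.repeat(np.arange(n_rows), n_cols)
    cols = 2 * np.tile(np.arange(n_cols), n_rows) + rows % 2
    x, y = lattice_pixel_coords(rows, cols, pitch_px)
    barcodes = [f"SPOT-{r:03d}-{c:03d}" for r, c in zip(rows, cols)]
    return pd.DataFrame(
        {
            "array_row": rows,
            "array_col": cols,
            "pixel_x": x,
            "pixel_y": y,
            "in_tissue": True,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
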