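"""Cross-modality image integration by binarized-mask alignment.

Serial sections imaged on two platforms (H&E-stained spot array vs
multiplexed immunofluorescence) are integrated in four steps: binarize
each image into a tissue mask (removing the printed fiducial frame from
the H&E side), find the similarity transform (scale, rotation,
translation) maximizing the intersection-over-union of the two masks,
expose the transform and its exact inverse as coordinate mappings, and
map per-cell signals onto spots (and back).

Transform convention, serialized with every transform: the point is
scaled, then rotated by θ (counter-clockwise in x-y coordinates) about
the recorded center, then translated:

    p' = s · R(θ) · (p − c) + c + t

The optimizer is a coarse grid over (scale, θ) with translation from mask
cross-correlation, followed by a deterministic shrinking pattern search on
all four parameters under the full-resolution IoU objective; masks are
resampled nearest-neighbor so the objective stays set-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
from scipy.spatial import cKDTree
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.transform import ProjectiveTransform, warp

from tmeland.grid import SpotGrid


class RegistrationError(ValueError):
    pass


@dataclass
class BinaryMask:
    """Boolean tissue raster with provenance."""

    data: np.ndarray
    pixel_size_um: float | None = None
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2 or self.data.size == 0:
            raise RegistrationError("mask must be a non-empty 2D raster")
        if not self.data.any():
            raise RegistrationError("mask has no foreground pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SimilarityTransform:
    """Scale-rotation-translation map p' = s·R(θ)·(p − c) + c + t."""

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (self.scale > 0):
            raise RegistrationError("scale must be positive")
        params = (self.scale, self.rotation_deg, *self.translation, *self.center)
        if not np.all(np.isfinite(params)):
            raise RegistrationError("non-finite transform parameters")
        self.scale = float(self.scale)
        self.rotation_deg = float(self.rotation_deg)
        self.translation = (float(self.translation[0]), float(self.translation[1]))
        self.center = (float(self.center[0]), float(self.center[1]))

    @property
    def matrix(self) -> np.ndarray:
        """3×3 homogeneous matrix acting on (x, y, 1) column vectors."""
        th = np.deg2rad(self.rotation_deg)
        a = self.scale * np.array(
            [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        )
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        b = c + t - a @ c
        m = np.eye(3)
        m[:2, :2] = a
        m[:2, 2] = b
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out

    def inverse(self) -> "SimilarityTransform":
        """Exact algebraic inverse (origin-centered parameterization)."""
        m = np.linalg.inv(self.matrix)
        tx, ty = m[:2, 2]
        return SimilarityTransform(
            scale=1.0 / self.scale,
            rotation_deg=-self.rotation_deg,
            translation=(float(tx), float(ty)),
            center=(0.0, 0.0),
        )

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation_deg": self.rotation_deg,
            "translation": list(self.translation),
            "center": list(self.center),
            "convention": "p' = s*R(theta)*(p - c) + c + t; x right, y down",
        }


@dataclass
class SearchSpace:
    """Coarse-grid and refinement settings for mask alignment."""

    scale_range: tuple[float, float] = (0.8, 1.25)
    scale_step: float = 0.025
    rotation_range: tuple[float, float] = (-20.0, 20.0)
    rotation_step: float = 1.0
    downsample: int = 4
    min_iou: float = 0.5


@dataclass
class AlignmentResult:
    transform: SimilarityTransform
    iou: float
    ok: bool
    message: str = ""


def make_mask(
    image: np.ndarray,
    modality: str = "he",
    channels: list[int] | None = None,
    invert: bool = False,
    remove_fiducials: bool = True,
    border_frac: float = 0.2,
    fiducial_area: tuple[int, int] = (9, 2000),
    min_circularity: float = 0.55,
    min_object_px: int = 16,
    max_hole_px: int = 64,
    pixel_size_um: float | None = None,
) -> BinaryMask:
    """Binarize an image into a tissue mask.

    H&E path (``modality="he"``): Otsu threshold of the grayscale image
    (``invert=True`` when tissue is dark on a bright background), then
    removal of fiducial artifacts — small, near-circular foreground
    components whose bounding box lies in the border frame (outer
    ``border_frac`` of the raster).  Multiplexed path
    (``modality="multiplex"``): pixelwise union (max projection) of the
    selected channels, then Otsu threshold.  Both paths finish with
    small-object removal and small-hole filling.
    """
    img = np.asarray(image, dtype=float)
    if modality == "multiplex":
        if img.ndim != 3:
            raise RegistrationError("multiplex path expects an (H, W, C) stack")
        chans = channels if channels is not None else list(range(img.shape[2]))
        img = img[:, :, chans].max(axis=2)
    elif img.ndim != 2:
        raise RegistrationError("he path expects a 2D grayscale image")
    if np.ptp(img) == 0:
        raise RegistrationError("image is constant: no foreground after thresholding")
    uniq = np.unique(img)
    thr = uniq[0] if len(uniq) == 2 else threshold_otsu(img)
    fg = (img <= thr) if invert else (img > thr)
    if not fg.any():
        raise RegistrationError("no foreground after thresholding")
    if modality == "he" and remove_fiducials:
        fg = _remove_fiducials(fg, border_frac, fiducial_area, min_circularity)
    fg = morphology.remove_small_objects(fg, max_size=min_object_px - 1)
    fg = morphology.remove_small_holes(fg, max_size=max_hole_px - 1)
    if not fg.any():
        raise RegistrationError("mask empty after cleanup")
    return BinaryMask(fg, pixel_size_um, provenance=modality)


def _remove_fiducials(
    fg: np.ndarray,
    border_frac: float,
    area_bounds: tuple[int, int],
    min_circularity: float,
) -> np.ndarray:
    """Drop small near-circular components confined to the border frame."""
    h, w = fg.shape
    bh, bw = border_frac * h, border_frac * w
    lab = measure.label(fg, connectivity=2)
    out = fg.copy()
    for prop in measure.regionprops(lab):
        r0, c0, r1, c1 = prop.bbox
        in_border = r1 <= bh or r0 >= h - bh or c1 <= bw or c0 >= w - bw
        if not in_border:
            continue
        if not (area_bounds[0] <= prop.area <= area_bounds[1]):
            continue
        perim = max(prop.perimeter, 1.0)
        circularity = 4 * np.pi * prop.area / perim**2
        if circularity >= min_circularity:
            out[lab == prop.label] = False
    return out


def _warp_mask(mask: np.ndarray, tf: SimilarityTransform, shape) -> np.ndarray:
    """Nearest-neighbor warp of a boolean mask by the forward transform."""
    inv = np.linalg.inv(tf.matrix)
    # warp's coordinate maps act on (col, row) = (x, y)
    w = warp(
        mask.astype(float),
        ProjectiveTransform(matrix=inv),
        output_shape=shape,
        order=0,
        preserve_range=True,
        cval=0.0,
    )
    return w > 0.5


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


def align_masks(
    mask_a: BinaryMask,
    mask_b: BinaryMask,
    search: SearchSpace | None = None,
) -> AlignmentResult:
    """Find the similarity transform maximizing IoU(T(A), B).

    Deterministic: a coarse grid over (scale, rotation) — the best
    translation for each grid point comes from the cross-correlation of
    downsampled masks — followed by a shrinking pattern search over all
    four parameters at full resolution.  An achieved IoU below
    ``search.min_iou`` yields ``ok=False`` rather than a silent result.
    """
    search = search or SearchSpace()
    A, B = mask_a.data, mask_b.data
    k = max(1, int(search.downsample))
    a_ds = _block_reduce_max(A, k)
    b_ds = _block_reduce_max(B, k)
    center = ((A.shape[1] - 1) / 2.0, (A.shape[0] - 1) / 2.0)
    center_ds = ((a_ds.shape[1] - 1) / 2.0, (a_ds.shape[0] - 1) / 2.0)

    scales = np.arange(
        search.scale_range[0], search.scale_range[1] + 1e-9, search.scale_step
    )
    rotations = np.arange(
        search.rotation_range[0], search.rotation_range[1] + 1e-9, search.rotation_step
    )
    bf = b_ds.astype(float)
    best = None
    for s in scales:
        for th in rotations:
            tf = SimilarityTransform(s, th, (0.0, 0.0), center_ds)
            aw = _warp_mask(a_ds, tf, b_ds.shape)
            if not aw.any():
                continue
            corr = scipy.signal.correlate(bf, aw.astype(float), mode="full", method="fft")
            iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
            dy = iy - (aw.shape[0] - 1)
            dx = ix - (aw.shape[1] - 1)
            tf2 = SimilarityTransform(s, th, (float(dx), float(dy)), center_ds)
            score = _iou(_warp_mask(a_ds, tf2, b_ds.shape), b_ds)
            if best is None or score > best[0]:
                best = (score, s, th, dx * k, dy * k)
    if best is None:
        return AlignmentResult(
            SimilarityTransform(center=center), 0.0, False, "coarse search found no overlap"
        )

    _, s, th, tx, ty = best
    params = np.array([s, th, tx, ty], dtype=float)
    steps = np.array([search.scale_step, search.rotation_step, float(k), float(k)])
    min_steps = np.array([0.002, 0.05, 0.25, 0.25])

    def objective(p):
        tf = SimilarityTransform(p[0], p[1], (p[2], p[3]), center)
        return _iou(_warp_mask(A, tf, B.shape), B)

    cur = objective(params)
    while np.any(steps > min_steps):
        improved = False
        for i in range(4):
            for sgn in (1.0, -1.0):
                trial = params.copy()
                trial[i] += sgn * steps[i]
                # refinement stays inside the declared search space
                if not (search.scale_range[0] <= trial[0] <= search.scale_range[1]):
                    continue
                if not (
                    search.rotation_range[0] <= trial[1] <= search.rotation_range[1]
                ):
                    continue
                val = objective(trial)
                if val > cur:
                    params, cur, improved = trial, val, True
        if not improved:
            steps = np.maximum(steps / 2.0, min_steps * 0.999)

    tf = SimilarityTransform(params[0], params[1], (params[2], params[3]), center)
    ok = cur >= search.min_iou
    msg = "" if ok else f"achieved IoU {cur:.3f} below floor {search.min_iou}"
    return AlignmentResult(tf, float(cur), ok, msg)


def _block_reduce_max(mask: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return mask
    h, w = mask.shape
    hh, ww = (h // k) * k, (w // k) * k
    return mask[:hh, :ww].reshape(hh // k, k, ww // k, k).max(axis=(1, 3))


def transform_coords(
    transform: SimilarityTransform, points: np.ndarray, direction: str = "forward"
) -> np.ndarray:
    """Apply the transform (or its exact inverse) to (x, y) points."""
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise RegistrationError("non-finite points")
    if direction == "forward":
        return transform.apply(pts)
    if direction == "inverse":
        return transform.inverse().apply(pts)
    raise RegistrationError(f"unknown direction {direction!r}")


def map_signals(
    grid: SpotGrid,
    cells: pd.DataFrame,
    transform: SimilarityTransform | AlignmentResult,
    markers: list[str] | None = None,
    spot_radius_px: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Positionally integrate per-cell signals onto spots.

    ``cells`` carries ``x``/``y`` centroids in the target-modality frame
    plus marker intensity columns; the transform maps spot-image
    coordinates into that frame (cells travel back through its inverse).
    Each cell is assigned to the nearest spot center within one spot
    radius (default pitch/2), else left unassigned.

    Returns (per-spot mean intensity per marker, per-cell assigned spot id
    with NaN for unassigned).  Refuses an alignment flagged as failed.
    """
    if isinstance(transform, AlignmentResult):
        if not transform.ok:
            raise RegistrationError(
                f"refusing to map through a failed alignment: {transform.message}"
            )
        transform = transform.transform
    if spot_radius_px is None:
        spot_radius_px = grid.pitch_px / 2.0
    if markers is None:
        markers = [c for c in cells.columns if c not in ("x", "y")]
    cell_xy = cells[["x", "y"]].to_numpy(dtype=float)
    in_spot_frame = transform.inverse().apply(cell_xy)
    tree = cKDTree(grid.positions_px)
    dist, idx = tree.query(in_spot_frame)
    assigned = dist <= spot_radius_px
    spot_ids = pd.Series(
        np.where(assigned, grid.spot_ids.to_numpy(object)[idx], np.nan),
        index=cells.index,
        name="spot_id",
    )
    per_spot = (
        cells.loc[assigned, markers]
        .groupby(spot_ids[assigned])
        .mean()
        .reindex(grid.spot_ids)
    )
    return per_spot, spot_ids
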