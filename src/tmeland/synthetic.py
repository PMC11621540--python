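"""Synthetic data with planted ground truth for the whole pipeline.

Real spot-level tumor sections of this kind sit behind controlled access,
so every input the pipeline consumes can be generated here instead:
hex-lattice sections with cluster regions and signature-driven
overdispersed (gamma-Poisson) counts, monotone score gradients planted
along a spatial path, dense proliferative/invasive enclaves, paired
binary masks related by a known similarity transform (with fiducial-dot
artifacts on the H&E-proxy mask only), and segmented-cell intensity
tables with planted total-intensity outliers.  Every generator is
deterministic given its seed and records what it planted.

The generators emulate structure, not histology: counts are independent
across genes given the planted means, expression boundaries are sharp,
and mask pairs differ only by a similarity transform — see the package
methods note for what this does and does not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tmeland.config import SignatureSet, default_signatures
from tmeland.grid import SpotGrid, full_lattice, hex_distance
from tmeland.registration import SimilarityTransform, _warp_mask
from tmeland.trajectory import build_trajectory, project_spots


class SyntheticError(ValueError):
    pass


@dataclass
class Rect:
    """Half-open rectangle in (array_row, column-index) space.

    Column index j counts lattice columns within a row (array_col =
    2 j + row parity), so rectangles tile the lattice without parity gaps.
    """

    r0: int
    r1: int
    j0: int
    j1: int

    def contains(self, rows: np.ndarray, js: np.ndarray) -> np.ndarray:
        return (rows >= self.r0) & (rows < self.r1) & (js >= self.j0) & (js < self.j1)

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.r1 <= other.r0
            or other.r1 <= self.r0
            or self.j1 <= other.j0
            or other.j1 <= self.j0
        )


@dataclass
class GradientPlan:
    """Monotone signature gradients along an ordered cluster path.

    ``effects`` maps signature name to the log2 fold-change amplitude
    reached at t = 1 (negative amplitudes fall along the path).
    """

    path: list
    effects: dict[str, float]


@dataclass
class EnclaveSpec:
    feature_class: str  # "proliferative" | "invasive"
    center: tuple[int, int]  # (array_row, array_col)
    n_spots: int


@dataclass
class SectionConfig:
    """Study conditions for one synthetic section."""

    n_rows: int = 30
    n_cols: int = 30
    cluster_layout: dict = field(default_factory=dict)  # cluster id -> Rect
    background_cluster: str = "c0"
    signature_plan: dict = field(default_factory=dict)  # cluster -> {sig: log2FC}
    gradient_plan: GradientPlan | None = None
    enclave_plan: list[EnclaveSpec] = field(default_factory=list)
    scatter_plan: dict = field(default_factory=dict)  # class -> n isolated spots
    enclave_log2fc: float = 3.0
    n_background_genes: int = 200
    baseline_mean: float = 2.0
    dispersion: float = 2.0
    pitch_px: float = 100.0
    seed: int = 0


@dataclass
class GroundTruth:
    """What a generator planted, for downstream recovery checks."""

    cluster: pd.Series | None = None
    feature_class: pd.Series | None = None
    enclaves: list = field(default_factory=list)  # (class, [spot ids])
    scattered: dict = field(default_factory=dict)  # class -> [spot ids]
    gradients: list = field(default_factory=list)  # (signature, t0, t1, sign)
    spot_t: pd.Series | None = None
    transform: SimilarityTransform | None = None
    mask_clean: np.ndarray | None = None
    outlier_flags: pd.Series | None = None


_CLASS_TO_SIGNATURE = {"proliferative": "proliferative", "invasive": "invasive"}


def gen_section(
    config: SectionConfig, signatures: SignatureSet | None = None
) -> tuple[SpotGrid, pd.DataFrame, GroundTruth]:
    """Generate a hex section: grid with clusters, counts, ground truth.

    Counts are gamma-Poisson (negative-binomial-like): gene g in spot s
    has mean ``baseline_g × 2^(planted log2 effects)`` and dispersion
    ``config.dispersion`` (variance μ + μ²/dispersion).  Elevations come
    from the per-cluster signature plan, the gradient plan (multiplier
    2^(amplitude × t) along the cluster-centroid path) and planted
    enclaves/scattered spots of the proliferative/invasive classes.
    """
    signatures = signatures or default_signatures()
    rng = np.random.default_rng(config.seed)
    table = full_lattice(config.n_rows, config.n_cols, config.pitch_px)
    rows = table["array_row"].to_numpy()
    cols = table["array_col"].to_numpy()
    js = (cols - rows % 2) // 2

    # cluster assignment from rectangular footprints over a background
    layout = list(config.cluster_layout.items())
    for i in range(len(layout)):
        for k in range(i + 1, len(layout)):
            if layout[i][1].overlaps(layout[k][1]):
                raise SyntheticError(
                    f"cluster footprints {layout[i][0]!r} and {layout[k][0]!r} overlap"
                )
    cluster = np.full(len(table), config.background_cluster, dtype=object)
    for cid, rect in layout:
        cluster[rect.contains(rows, js)] = cid
    table["cluster"] = cluster
    grid = SpotGrid(table, pitch_px=config.pitch_px)

    sig_names = [s.name for s in signatures]
    unknown = [
        s
        for plan in config.signature_plan.values()
        for s in plan
        if s not in sig_names
    ]
    if config.gradient_plan:
        unknown += [s for s in config.gradient_plan.effects if s not in sig_names]
    if unknown:
        raise SyntheticError(f"signature plan references unknown signatures: {unknown}")

    genes = sorted(signatures.all_genes()) + [
        f"BG_{i:04d}" for i in range(1, config.n_background_genes + 1)
    ]
    gene_idx = {g: i for i, g in enumerate(genes)}
    baseline = config.baseline_mean * rng.lognormal(0.0, 0.5, size=len(genes))

    log2_effect = np.zeros((len(table), len(genes)))

    def elevate(spot_mask: np.ndarray, signature: str, lfc: float) -> None:
        idx = [gene_idx[g] for g in signatures.genes(signature) if g in gene_idx]
        log2_effect[np.ix_(spot_mask, idx)] += lfc

    for cid, plan in config.signature_plan.items():
        mask = cluster == cid
        if not mask.any():
            raise SyntheticError(f"signature plan references empty cluster {cid!r}")
        for sig, lfc in plan.items():
            elevate(mask, sig, lfc)

    truth = GroundTruth(
        cluster=pd.Series(cluster, index=table.index, name="cluster"),
        feature_class=pd.Series("none", index=table.index, name="feature_class"),
    )

    if config.gradient_plan is not None:
        path = build_trajectory(grid, config.gradient_plan.path)
        proj = project_spots(path, grid, corridor_width=1e12)  # t for every spot
        on_path = np.isin(cluster, config.gradient_plan.path)
        t = proj["t"].to_numpy()
        truth.spot_t = pd.Series(np.where(on_path, t, np.nan), index=table.index)
        for sig, amp in config.gradient_plan.effects.items():
            log2_effect[np.ix_(on_path, [gene_idx[g] for g in signatures.genes(sig)])] += (
                amp * t[on_path, None]
            )
            truth.gradients.append((sig, 0.0, 1.0, 1 if amp > 0 else -1))

    rc = np.column_stack([rows, cols])
    occupied = np.zeros(len(table), dtype=bool)
    for spec in config.enclave_plan:
        members = _grow_enclave(rc, spec.center, spec.n_spots)
        if occupied[members].any():
            raise SyntheticError("enclave footprints overlap")
        occupied[members] = True
        mask = np.zeros(len(table), dtype=bool)
        mask[members] = True
        elevate(mask, _CLASS_TO_SIGNATURE[spec.feature_class], config.enclave_log2fc)
        ids = list(table.index[members])
        truth.enclaves.append((spec.feature_class, ids))
        truth.feature_class.iloc[members] = spec.feature_class

    for cls, n in config.scatter_plan.items():
        chosen = _scatter_spots(rc, occupied, n, rng, min_separation=6)
        occupied[chosen] = True
        mask = np.zeros(len(table), dtype=bool)
        mask[chosen] = True
        elevate(mask, _CLASS_TO_SIGNATURE[cls], config.enclave_log2fc)
        truth.scattered[cls] = list(table.index[chosen])
        truth.feature_class.iloc[chosen] = cls

    mu = baseline[None, :] * np.power(2.0, log2_effect)
    lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
    counts = pd.DataFrame(
        rng.poisson(lam).astype(np.int64), index=table.index, columns=genes
    )
    return grid, counts, truth


def _grow_enclave(rc: np.ndarray, center: tuple[int, int], n_spots: int) -> np.ndarray:
    """Indices of the n_spots lattice spots nearest (hex) to the center,
    ties broken by (row, col) for determinism."""
    if n_spots > len(rc):
        raise SyntheticError("enclave does not fit inside the lattice")
    d = hex_distance(center[0], center[1], rc[:, 0], rc[:, 1])
    if d.min() > 0:
        raise SyntheticError(f"enclave center {center} is not a lattice spot")
    order = np.lexsort((rc[:, 1], rc[:, 0], d))
    return order[:n_spots]


def _scatter_spots(
    rc: np.ndarray,
    occupied: np.ndarray,
    n: int,
    rng: np.random.Generator,
    min_separation: int,
) -> np.ndarray:
    chosen: list[int] = []
    candidates = rng.permutation(len(rc))
    for i in candidates:
        if len(chosen) == n:
            break
        if occupied[i]:
            continue
        near_occ = hex_distance(
            rc[i, 0], rc[i, 1], rc[occupied, 0], rc[occupied, 1]
        )
        if occupied.any() and near_occ.min() < min_separation:
            continue
        if chosen:
            dd = hex_distance(
                rc[i, 0], rc[i, 1], rc[chosen, 0], rc[chosen, 1]
            )
            if dd.min() < min_separation:
                continue
        chosen.append(i)
    if len(chosen) < n:
        raise SyntheticError("could not place all scattered spots")
    return np.asarray(chosen, dtype=int)


def gen_mask_pair(
    shape: tuple[int, int] = (256, 256),
    scale: float = 1.0,
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    n_fiducials: int = 0,
    n_blobs: int = 5,
    fiducial_radius: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Paired binary masks related by a known similarity transform.

    Mask A holds an asymmetric tissue blob plus ``n_fiducials``
    disc-shaped fiducial artifacts along the raster border (the H&E
    proxy); mask B is the blob alone resampled through the recorded
    transform (about the raster center).  Returns (maskA, maskB, truth)
    as uint8 0/255 images; ``truth.mask_clean`` is A without fiducials.
    """
    if not (scale > 0):
        raise SyntheticError("scale must be positive")
    if abs(rotation_deg) > 180:
        raise SyntheticError("|rotation| must be <= 180 degrees")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    blob = np.zeros(shape, dtype=bool)
    # blob stays clear of the border band so fiducials never touch tissue
    for _ in range(n_blobs):
        cy = rng.uniform(0.35 * h, 0.65 * h)
        cx = rng.uniform(0.35 * w, 0.65 * w)
        ay = rng.uniform(0.08, 0.16) * h
        ax = rng.uniform(0.08, 0.16) * w
        th = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        blob |= (u / ax) ** 2 + (v / ay) ** 2 <= 1.0

    tf = SimilarityTransform(
        scale, rotation_deg, tuple(translation), ((w - 1) / 2.0, (h - 1) / 2.0)
    )
    mask_b = _warp_mask(blob, tf, shape)
    if not mask_b.any():
        raise SyntheticError("transform maps the tissue fully outside the raster")

    mask_a = blob.copy()
    margin = 3 * fiducial_radius
    perimeter = _border_positions(h, w, margin, n_fiducials)
    for cy, cx in perimeter:
        mask_a |= (xx - cx) ** 2 + (yy - cy) ** 2 <= fiducial_radius**2

    truth = GroundTruth(transform=tf, mask_clean=blob)
    return (
        (mask_a * np.uint8(255)),
        (mask_b * np.uint8(255)),
        truth,
    )


def _border_positions(h: int, w: int, margin: int, n: int) -> list[tuple[float, float]]:
    """n points evenly spaced along the border rectangle inset by margin."""
    if n == 0:
        return []
    x0, x1 = margin, w - 1 - margin
    y0, y1 = margin, h - 1 - margin
    per = 2 * (x1 - x0) + 2 * (y1 - y0)
    pts = []
    for i in range(n):
        d = per * i / n
        if d < x1 - x0:
            pts.append((y0, x0 + d))
            continue
        d -= x1 - x0
        if d < y1 - y0:
            pts.append((y0 + d, x1))
            continue
        d -= y1 - y0
        if d < x1 - x0:
            pts.append((y1, x1 - d))
            continue
        d -= x1 - x0
        pts.append((y1 - d, x0))
    return pts


def gen_cell_table(
    n_cells: int,
    n_markers: int = 10,
    outlier_fraction: float = 0.0,
    outlier_mode: str = "high",
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Segmented-cell intensity table with planted total-intensity outliers.

    Bulk intensities are lognormal per marker; outlier cells have every
    marker scaled ×8 (``outlier_mode="high"``), ×0.05 (``"low"``) or an
    even split (``"both"``), pushing their totals outside the bulk.
    """
    if n_cells < 10:
        raise SyntheticError("n_cells must be >= 10 (percentile filter undefined)")
    if not (0 <= outlier_fraction < 0.5):
        raise SyntheticError("outlier_fraction must lie in [0, 0.5)")
    if outlier_mode not in ("high", "low", "both"):
        raise SyntheticError(f"unknown outlier_mode {outlier_mode!r}")
    rng = np.random.default_rng(seed)
    markers = [f"marker_{i:02d}" for i in range(1, n_markers + 1)]
    base = rng.lognormal(mean=2.0, sigma=0.25, size=(n_cells, n_markers))
    idx = pd.Index([f"cell_{i:05d}" for i in range(n_cells)], name="cell_id")
    flags = np.zeros(n_cells, dtype=bool)
    n_out = int(round(outlier_fraction * n_cells))
    if n_out:
        out_idx = rng.choice(n_cells, size=n_out, replace=False)
        flags[out_idx] = True
        factors = np.full(n_out, 8.0)
        if outlier_mode == "low":
            factors[:] = 0.05
        elif outlier_mode == "both":
            factors[1::2] = 0.05
        base[out_idx] *= factors[:, None]
    table = pd.DataFrame(base, index=idx, columns=markers)
    table.insert(0, "x", rng.uniform(0, 1000, n_cells))
    table.insert(1, "y", rng.uniform(0, 1000, n_cells))
    truth = GroundTruth(outlier_flags=pd.Series(flags, index=idx, name="outlier"))
    return table, truth


# ---------------------------------------------------------------------------
# canned study conditions used by the test-bench and the CLI simulator


def strip_layout(cluster_ids: list, n_rows: int, n_cols: int) -> dict:
    """Vertical-strip cluster footprints spanning the lattice left to right."""
    edges = np.linspace(0, n_cols, len(cluster_ids) + 1).astype(int)
    return {
        cid: Rect(0, n_rows, int(edges[i]), int(edges[i + 1]))
        for i, cid in enumerate(cluster_ids)
    }


def gradient_section_config(seed: int = 0, n_rows: int = 24, n_cols: int = 60) -> SectionConfig:
    """A section with a rising invasive and falling B-cell gradient along a
    four-cluster left-to-right path — the planted analog of an invasion
    front displacing immune cells along the tumor's spatial trajectory."""
    path = ["c1", "c2", "c3", "c4"]
    return SectionConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        cluster_layout=strip_layout(path, n_rows, n_cols),
        gradient_plan=GradientPlan(
            path=path, effects={"invasive": 3.0, "B cell": -3.0}
        ),
        seed=seed,
    )


def enclave_section_config(
    seed: int = 0,
    n_rows: int = 40,
    n_cols: int = 40,
    enclave_spots: int = 40,
    n_scattered: int = 5,
) -> SectionConfig:
    """A 40×40 early-lesion-like section: one dense invasive enclave plus
    a few isolated invasive spots on a quiet background."""
    center_row = n_rows // 2
    center_col = 2 * (n_cols // 2) + center_row % 2
    return SectionConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        enclave_plan=[EnclaveSpec("invasive", (center_row, center_col), enclave_spots)],
        scatter_plan={"invasive": n_scattered},
        seed=seed,
    )
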