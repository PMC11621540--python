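"""Possibly-malignant region calling for early-stage (AIS/MIA) sections.

Early lesions have no established spatial trajectory, so dense clusters of
proliferative or invasive spots are sought directly: each spot receives a
local enrichment score — a distance-weighted count of target-class spots
in its hex neighborhood — and a section-level threshold (70% of the
section's maximum score, floored at 10) selects spots whose connected
components larger than 15 spots become "possibly malignant-proliferative"
or "possibly malignant-invasive" regions.  Both the score cutoff and the
size cutoff are strict inequalities.

The kernel counts the spot itself and each hex ring of neighbors out to
a maximum ring, with strictly decreasing integer weights (default radius
6, weights 12 down to 6 — a support of ~0.6 mm whose flat taper keeps
member scores of an enclave-scale cluster comparable, so the
fraction-of-max threshold retains enclave boundaries rather than eroding
them).  The kernel is additive over target spots: the field of a set of
targets is the sum of the single-target fields.

Regions are then characterized by rank-sum differential expression against
the rest of the section on library-size log-normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats
from statsmodels.stats.multitest import multipletests

from tmeland.grid import SpotGrid, ring_offsets
from tmeland.normalize import log_normalize  # noqa: F401  (module surface)
from tmeland.scoring import SpotLabeling

PROLIFERATIVE = "proliferative"
INVASIVE = "invasive"


class RegionError(ValueError):
    pass


@dataclass
class EnrichmentField:
    """Per-spot local enrichment score for one target class."""

    scores: pd.Series
    target_class: str
    radius: int
    weights: tuple[float, ...]

    @property
    def max_score(self) -> float:
        return float(self.scores.max())


@dataclass
class MalignantRegion:
    """A connected above-threshold component of the enrichment field."""

    label: str
    spot_ids: list
    section: str
    threshold: float

    @property
    def size(self) -> int:
        return len(self.spot_ids)


def local_enrichment(
    grid: SpotGrid,
    labeling: SpotLabeling,
    target_class: str = INVASIVE,
    radius: int = 6,
    weights: tuple[float, ...] = (12.0, 11.0, 10.0, 9.0, 8.0, 7.0, 6.0),
) -> EnrichmentField:
    """Distance-weighted count of target-class spots around every spot.

    score(s) = Σ over target spots u with hexdist(s, u) <= radius of
    weights[hexdist(s, u)].  The spot itself counts at ring 0.  Weights
    must be strictly decreasing with ring, one per ring 0..radius.
    """
    if radius < 0:
        raise RegionError("radius must be non-negative")
    if len(weights) != radius + 1:
        raise RegionError("weights must have length radius + 1")
    if any(b >= a for a, b in zip(weights, weights[1:])):
        raise RegionError("weights must be strictly decreasing with ring")
    labels = labeling.labels.reindex(grid.spot_ids)
    rc = grid.array_coords
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(rc)}
    scores = np.zeros(grid.n_spots)
    target_idx = np.flatnonzero((labels == target_class).to_numpy())
    offsets = [(ring, ring_offsets(ring)) for ring in range(radius + 1)]
    # additive superposition: each target spot deposits its kernel
    for i in target_idx:
        r, c = int(rc[i, 0]), int(rc[i, 1])
        for ring, offs in offsets:
            w = weights[ring]
            for dr, dc in offs:
                j = index.get((r + dr, c + dc))
                if j is not None:
                    scores[j] += w
    return EnrichmentField(
        scores=pd.Series(scores, index=grid.spot_ids, name="local_enrichment"),
        target_class=target_class,
        radius=radius,
        weights=tuple(weights),
    )


def enrichment_threshold(
    field: EnrichmentField, frac_of_max: float = 0.7, floor: float = 10.0
) -> float:
    """Section-level score threshold: frac_of_max × the section maximum,
    raised to ``floor`` whenever that product falls below it."""
    if len(field.scores) == 0:
        raise RegionError("empty enrichment field")
    m = field.max_score
    if m == 0:
        import warnings

        warnings.warn(
            "all-zero enrichment field: threshold falls back to the floor; "
            "no regions will pass",
            stacklevel=2,
        )
    value = frac_of_max * m
    return float(value if value >= floor else floor)


def extract_regions(
    grid: SpotGrid,
    field: EnrichmentField,
    threshold: float,
    min_region_spots: int = 15,
    section: str = "section",
) -> list[MalignantRegion]:
    """Connected components of spots scoring strictly above threshold,
    reported when strictly larger than ``min_region_spots``.

    Connectivity is 6-neighbor hex adjacency.  Regions are ordered by
    size (largest first), ties by first spot id.
    """
    scores = field.scores.reindex(grid.spot_ids).to_numpy()
    above = scores > threshold
    if not above.any():
        return []
    pairs = grid.adjacency_pairs()
    keep = above[pairs[:, 0]] & above[pairs[:, 1]] if len(pairs) else np.zeros(0, bool)
    sel = np.flatnonzero(above)
    remap = -np.ones(grid.n_spots, dtype=int)
    remap[sel] = np.arange(len(sel))
    p = pairs[keep]
    adj = scipy.sparse.coo_matrix(
        (np.ones(len(p)), (remap[p[:, 0]], remap[p[:, 1]])),
        shape=(len(sel), len(sel)),
    )
    n_comp, comp = scipy.sparse.csgraph.connected_components(adj, directed=False)
    label = f"possibly malignant-{field.target_class}"
    regions = []
    ids = grid.spot_ids.to_numpy()
    for k in range(n_comp):
        members = sel[comp == k]
        if len(members) > min_region_spots:
            regions.append(
                MalignantRegion(label, list(ids[members]), section, float(threshold))
            )
    regions.sort(key=lambda r: (-r.size, str(r.spot_ids[0]) if r.spot_ids else ""))
    return regions


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration (no ties, both groups <= 25) via the
    Mann-Whitney exact distribution; otherwise the tie-corrected normal
    approximation without continuity correction, so identical groups give
    p = 1 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and max(len(x), len(y)) <= 25:
        return float(
            scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    p = float(res.pvalue)
    return 1.0 if not np.isfinite(p) else min(p, 1.0)


def deg_wilcoxon(
    normalized: pd.DataFrame,
    in_region: pd.Series | np.ndarray,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Differential expression between in-region and out-of-region spots.

    Per gene: two-sided rank-sum p, Benjamini–Hochberg adjusted p, and
    log2FC = log2((mean expm1 in + pseudo) / (mean expm1 out + pseudo))
    computed on the de-logged normalized expression (pseudo documented,
    default 1).  Both groups must have at least 3 spots.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``p``,
    ``p_adj``, sorted by ascending p then descending |log2fc|.
    """
    mask = np.asarray(
        in_region.reindex(normalized.index) if isinstance(in_region, pd.Series) else in_region,
        dtype=bool,
    )
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < 3 or n_out < 3:
        raise RegionError(f"both groups need >= 3 spots (got {n_in} vs {n_out})")
    data = normalized.to_numpy(dtype=float)
    xin, xout = data[mask], data[~mask]
    expm_in = np.expm1(xin).mean(axis=0)
    expm_out = np.expm1(xout).mean(axis=0)
    log2fc = np.log2((expm_in + pseudo) / (expm_out + pseudo))
    pvals = np.array(
        [_rank_sum_p(xin[:, g], xout[:, g]) for g in range(data.shape[1])]
    )
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "p_adj": p_adj}, index=normalized.columns
    )
    order = (
        out.assign(_abs=np.abs(out["log2fc"]))
        .sort_values(["p", "_abs"], ascending=[True, False])
        .index
    )
    return out.loc[order]


def compare_section_maxima(maxima: pd.Series, groups: pd.Series) -> float:
    """Two-sided rank-sum p comparing per-section maximum enrichment
    scores between two groups (e.g. early AIS/MIA vs invasive sections).

    No multiple-comparison adjustment is applied.  Each group needs at
    least 2 sections.
    """
    groups = groups.reindex(maxima.index)
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise RegionError(f"need exactly 2 groups, got {list(levels)}")
    x = maxima[groups == levels[0]].to_numpy(dtype=float)
    y = maxima[groups == levels[1]].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise RegionError("each group needs >= 2 sections")
    return _rank_sum_p(x, y)
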