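# Methods

This note records the models, conventions and numerical choices behind
`tmeland`, and what the synthetic-data tests do and do not demonstrate.

## Lattice and coordinate conventions

Spots live on a hexagonal lattice in the Visium array-coordinate
convention: integer `(array_row, array_col)` with shared parity
(row + col even); the six nearest neighbors of `(r, c)` are `(r, c ± 2)`
and `(r ± 1, c ± 1)`. Hex graph distance is computed in cube coordinates
(`x = (c − r)/2`, `z = r`, `y = −x − z`; distance = half the L1 norm).
All coordinates are 0-based. Pixel coordinates follow the raster
convention (origin top-left, y down); one unit of hex distance equals one
spot pitch (100 µm physically; `pitch_px` in images). Spot capture areas
are 55 µm discs, so the nearest-spot assignment radius during signal
mapping defaults to pitch/2.

## Spot scoring

**PAGE.** Counts are normalized per spot to the median library size and
log2(x+1)-transformed; fold changes are taken against each gene's mean
across spots. The score `(S̄_m − μ)·√m/δ` uses the sample standard
deviation (ddof = 1) for δ, the convention of the enrichment tools this
statistic comes from. Spots with δ = 0 (e.g. a constant matrix) are
flagged degenerate and scored 0 instead of propagating NaN; the
normalization used and the per-signature m are recorded in the
`ScoreTable` so outputs are self-describing.

**Module scores.** Mean normalized expression of a gene set minus the
mean of control genes, each set gene contributing `n_ctrl = 100` controls
drawn with replacement from its own average-expression bin (`n_bins = 24`
equal-frequency bins) — the standard bin-matched construction with the
cited toolchain's default parameters. Drawing with replacement keeps the
control pool well-defined when a bin is smaller than `n_ctrl`.

**Classification.** A spot takes the argmax-scoring feature when that
score is ≥ `min_score` (default 2.0 on the z-like PAGE scale; the
labeling cutoff is not dictated by the statistic, so it is explicit and
configurable), else "unassigned". Exact ties resolve by a fixed priority:
tumor features before microenvironment features, lexicographic within
each — deterministic and recorded in the score table.

## Trajectory landscapes

The trajectory is a polyline through cluster centroids in a
user-supplied order (the root is the most normal-like /
well-differentiated cluster); no graph learning is performed. Spots
project to their nearest polyline point when within a corridor (default
2 spot pitches — wide enough to catch the spot rows flanking the path,
narrow enough to stay local); exact distance ties between segments take
the lower t.

Profiles use 100 equal-width t bins; a bin's raw value is the mean score
of its spots, empty bins are linearly interpolated from non-empty
neighbors, and smoothing is a centered moving average that shrinks
symmetrically at the edges (window 1 = identity; constants are preserved
exactly). The default window is 11 bins: with ~2–4 projected spots per
bin at realistic spot density, shorter windows leave enough bin noise
that spurious trend reversals fragment genuinely monotone gradients;
window 11 removes most of that fragmentation while keeping real
inflections. Both `n_bins` and the window are configuration values.

"Inflection points" are trend reversals of the smoothed profile — bins
where the sign of the first difference changes, with differences below
1e-9 of the profile range treated as flat — rather than curvature zeros;
monotone runs between reversals carry a signed slope
`(v(t1) − v(t0))/(t1 − t0)`, and runs with |slope| ≥ the per-signature
threshold (default 0.02 per unit normalized trajectory length, a
stand-in users should calibrate per signature) are reported as TME
changes.

Two changes of different features overlapping in t with positive length
form a TME pair; touching intervals do not pair. `cor_st` adds the two
absolute slopes and takes a positive sign when the slopes agree in
direction. The source statistic defines the sign only for (+,+) and
(+,−); this package extends same-sign → positive, so a pair of jointly
*falling* features also counts as positively associated. For a given
feature pair on one trajectory the *dominant* pair (longest overlap) is
the headline association; aggregation across trajectories sums per-pair
contributions and flags feature pairs whose sign is consistent across
every trajectory where they occur. Reversing the cluster order negates
every slope and leaves every |cor_st| unchanged.

Multi-section inputs are handled by concatenating spot tables with a
section identifier; per-trajectory analysis is unchanged.

## Possibly-malignant regions

The local enrichment score of a spot is the weighted count of
target-class (proliferative or invasive) spots within hex-ring distance
R, the spot itself counting at ring 0; weights are strictly decreasing
integers per ring, and the field is additive over target spots. The
threshold rule and size rule are applied exactly as stated: threshold =
70% of the section maximum, set to 10 whenever that value is below 10;
regions are connected components (6-neighbor hex adjacency) of spots
scoring *strictly above* the threshold, reported when *strictly larger*
than 15 spots.

The default kernel is radius 6 with weights (12, 11, …, 6). The kernel is
the one genuinely open choice in this stage, and its support matters: a
narrow kernel (e.g. radius 2) makes interior spots of any compact
enclave score roughly twice its boundary spots, so a
fraction-of-maximum threshold at 70% always strips the outermost ring —
roughly half the members of an enclave at the ~40-spot scale — no matter
how dense the enclave is. A kernel whose support spans the enclave
(radius 6 ≈ 0.6 mm) with a flat taper keeps member scores comparable, so
the 70% rule separates enclaves from scattered spots without eroding
them. The kernel is configurable and recorded in every
`EnrichmentField`; the worked micro-examples in the tests use the compact
(3, 2, 1) kernel explicitly.

Differential expression between called regions and the rest of the
section uses library-size log-normalization `ln(1 + 10⁴·x/lib)`
(zero-library spots normalize to zeros, flagged), a two-sided Wilcoxon
rank-sum test per gene, and Benjamini–Hochberg adjustment. The rank-sum
p-value is exact (full Mann-Whitney null) when both groups have ≤ 25
observations and no ties; otherwise the tie-corrected normal
approximation *without* continuity correction is used, so identical
groups give p = 1 exactly. log2 fold changes compare de-logged group
means with a pseudocount of 1. Section-level comparisons of maximum
enrichment scores use the same two-sided test with no multiplicity
adjustment.

## Registration

Transforms are similarities `p' = s·R(θ)·(p − c) + c + t` (θ
counter-clockwise in x-y coordinates, applied scale → rotate → translate
about the recorded center), serialized with their convention; the
inverse is algebraic, so forward-then-inverse round trips are exact to
floating point. Masks come from Otsu thresholding (H&E path: optional
inversion for dark tissue; fiducial artifacts — small near-circular
components whose bounding boxes sit in the outer 20% border frame, with
configurable area and circularity bounds — are removed; multiplexed
path: max projection of the chosen channels), followed by small-object
removal and hole filling.

Alignment maximizes IoU(T(A), B) with nearest-neighbor resampling so the
objective stays set-based: a coarse grid over scale (0.8–1.25, step
0.025) and rotation (±20°, step 1°), translation per grid point from FFT
cross-correlation of 4× down-sampled masks, then a deterministic
shrinking pattern search over all four parameters at full resolution,
bounded by the declared search space (final steps 0.002 / 0.05° /
0.25 px). Alignments below `min_iou` (default 0.5) return an explicit
failure flag, and signal mapping refuses flagged transforms. On
synthetic mask pairs the optimizer recovers planted transforms to within
(0.01, 0.5°, 2 px) across seeds.

## Cell-table preprocessing

Cells whose total marker intensity is ≥ the 99th or ≤ the 1st percentile
of totals are removed; percentiles use linear interpolation (the default
of the surrounding toolchains — nearest-rank would shift membership by
at most one cell at these sizes), and coinciding percentiles skip the
filter with a warning rather than removing everything. CLR normalization
is per marker across cells (margin 2): `y = log1p(x) − mean(log1p(x))`,
so every marker column centers to zero exactly; log1p keeps zero
intensities defined. Per-cell centering (margin 1) is available behind a
flag. Downstream PCA/clustering is out of scope; the module ends at the
normalized table.

## Synthetic data: what it emulates, and what it does not

`gen_section` produces hex sections with rectangular cluster footprints,
gamma-Poisson counts (mean = per-gene lognormal baseline × planted
log2 effects; dispersion 2, variance μ + μ²/θ), per-cluster signature
elevations, monotone gradients along a cluster-centroid path (multiplier
`2^(amplitude·t)`), compact enclaves grown as the n nearest lattice
spots around a center, and isolated scattered spots. Default study
conditions: baseline mean 2 counts per gene (library sizes ~10³,
realistic for tumor-dense spots), 20 genes per signature, 200 background
genes, gradient amplitude ±3 log2 units, enclave elevation +3 log2
units; canned configurations provide a 24×60 gradient section and a
40×40 enclave section. `gen_mask_pair` draws an asymmetric union of
random ellipses, warps it by the requested similarity transform, and
stamps disc fiducials along the border of the un-warped mask only.
`gen_cell_table` plants total-intensity outliers by scaling whole cells
×8 or ×0.05. Every generator is bit-reproducible from its seed and
records its ground truth.

The generators emulate *structure*, not biology: genes are independent
given their means, cluster boundaries are sharp rectangles, gradients
are exactly exponential in t, masks differ by a pure similarity
transform (no tissue deformation, staining variation or section loss),
and cell intensities are independent lognormals. Passing tests therefore
demonstrate that each algorithm recovers what it is defined to recover
under its own assumptions — correct arithmetic, thresholds, geometry and
determinism — not that the pipeline is robust to the correlated noise,
deformation and annotation error of real sections.

## Known limitations

- The trajectory change detector still fragments noisy profiles into
  short monotone runs; the dominant-overlap pair is robust, but
  individual micro-segments can carry large noise slopes. A minimum
  segment span would suppress them at the cost of an extra parameter.
- Per-signature slope thresholds default to a single stand-in value and
  should be calibrated per dataset.
- Registration assumes a global similarity; serial-section deformation
  (non-rigid) is explicitly out of scope.
- The packaged PAGE signature lists are synthetic stand-ins matched to
  the simulator, not curated tumor signatures.
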