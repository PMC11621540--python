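import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmeland.grid import SpotGrid, full_lattice
from tmeland.trajectory import (
    ChangeSegment,
    ScoreProfile,
    TrajectoryError,
    aggregate_pairs,
    build_trajectory,
    cor_st,
    extract_profile,
    find_change_segments,
    pair_changes,
    project_spots,
)


def _grid_with_clusters(points: dict) -> SpotGrid:
    """Grid whose named clusters each hold one spot at given pixel coords."""
    rows, cols, px, py, cl = [], [], [], [], []
    for i, (name, (x, y)) in enumerate(points.items()):
        rows.append(0)
        cols.append(2 * i)
        px.append(x)
        py.append(y)
        cl.append(name)
    table = pd.DataFrame(
        {"array_row": rows, "array_col": cols, "pixel_x": px, "pixel_y": py,
         "in_tissue": True, "cluster": cl},
        index=[f"s{i}" for i in range(len(points))],
    )
    return SpotGrid(table)


def test_two_cluster_trajectory_geometry():
    grid = _grid_with_clusters({"a": (0, 0), "b": (3, 4)})
    path = build_trajectory(grid, ["a", "b"])
    assert path.total_length == pytest.approx(5.0)
    assert path.t_vertices == pytest.approx([0.0, 1.0])


def test_collinear_centroids_cumulative_t():
    grid = _grid_with_clusters({"a": (0, 0), "b": (1, 0), "c": (4, 0)})
    path = build_trajectory(grid, ["a", "b", "c"])
    assert path.t_vertices == pytest.approx([0.0, 0.25, 1.0])


def test_single_cluster_rejected(small_grid):
    with pytest.raises(TrajectoryError):
        build_trajectory(small_grid, ["left"])


def test_coincident_centroids_rejected():
    grid = _grid_with_clusters({"a": (0, 0), "b": (0, 0)})
    with pytest.raises(TrajectoryError, match="coincident"):
        build_trajectory(grid, ["a", "b"])


def _line_path(length=100.0):
    grid = _grid_with_clusters({"a": (0.0, 0.0), "b": (length, 0.0)})
    return build_trajectory(grid, ["a", "b"])


def _free_grid(points: np.ndarray) -> SpotGrid:
    n = len(points)
    table = pd.DataFrame(
        {"array_row": 0, "array_col": [2 * i for i in range(n)],
         "pixel_x": points[:, 0], "pixel_y": points[:, 1], "in_tissue": True},
        index=[f"p{i}" for i in range(n)],
    )
    return SpotGrid(table)


def test_projection_matches_dense_sampling_oracle():
    """Projection t equals a brute-force nearest point over a densely
    sampled polyline, to 1e-3."""
    verts = {"a": (0.0, 0.0), "b": (60.0, 30.0), "c": (100.0, 0.0)}
    grid_cl = _grid_with_clusters(verts)
    path = build_trajectory(grid_cl, ["a", "b", "c"])
    rng = np.random.default_rng(3)
    pts = rng.uniform([-10, -20], [110, 50], size=(40, 2))
    grid = _free_grid(pts)
    proj = project_spots(path, grid, corridor_width=1e6)

    # dense-sampling oracle
    vs = path.vertices
    samples, ts = [], []
    for i in range(len(vs) - 1):
        u = np.linspace(0, 1, 50_000, endpoint=False)[:, None]
        samples.append(vs[i] + u * (vs[i + 1] - vs[i]))
        ts.append(path.t_vertices[i] + u[:, 0] * (path.t_vertices[i + 1] - path.t_vertices[i]))
    samples = np.vstack(samples + [vs[-1:]])
    ts = np.concatenate(ts + [[1.0]])
    for p, t_got in zip(pts, proj["t"].to_numpy()):
        d = np.linalg.norm(samples - p, axis=1)
        assert abs(ts[np.argmin(d)] - t_got) < 1e-3


def test_spot_at_vertex_gets_vertex_t():
    verts = {"a": (0.0, 0.0), "b": (50.0, 0.0), "c": (50.0, 50.0)}
    path = build_trajectory(_grid_with_clusters(verts), ["a", "b", "c"])
    grid = _free_grid(np.array([[50.0, 0.0]]))
    proj = project_spots(path, grid, corridor_width=10.0)
    assert proj["t"].iloc[0] == pytest.approx(0.5)


def test_corridor_boundary_is_inclusive_exclusive():
    path = _line_path(100.0)
    grid = _free_grid(np.array([[50.0, 20.0], [50.0, 20.0 + 1e-6]]))
    proj = project_spots(path, grid, corridor_width=20.0)
    assert bool(proj["included"].iloc[0])
    assert not bool(proj["included"].iloc[1])
    assert np.isnan(proj["t"].iloc[1])


def test_corridor_width_must_be_positive(small_grid):
    path = build_trajectory(small_grid, ["left", "right"])
    with pytest.raises(TrajectoryError):
        project_spots(path, small_grid, corridor_width=0.0)


def _projections_linear(n=400, seed=0):
    """Spots spread along a 100-px horizontal line with t = x/100."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 100, n)
    pts = np.column_stack([x, np.zeros(n)])
    grid = _free_grid(pts)
    path = _line_path(100.0)
    return grid, project_spots(path, grid, corridor_width=5.0)


def test_constant_field_gives_flat_profile():
    grid, proj = _projections_linear()
    scores = pd.DataFrame({"sig": 3.5}, index=grid.spot_ids)
    prof = extract_profile(scores, proj, n_bins=50, window=5)["sig"]
    assert np.allclose(prof.smoothed, 3.5)


def test_linear_field_profile_is_linear_in_interior():
    grid, proj = _projections_linear(n=2000)
    t = proj["t"]
    scores = pd.DataFrame({"sig": 2.0 * t}, index=grid.spot_ids)
    prof = extract_profile(scores, proj, n_bins=50, window=5)["sig"]
    interior = slice(5, 45)
    fitted = np.polyval(
        np.polyfit(prof.t_centers[interior], prof.smoothed[interior], 1),
        prof.t_centers[interior],
    )
    assert np.max(np.abs(prof.smoothed[interior] - fitted)) < 0.02 * 2.0


def test_window_one_is_identity():
    grid, proj = _projections_linear()
    rng = np.random.default_rng(1)
    scores = pd.DataFrame({"sig": rng.normal(size=grid.n_spots)}, index=grid.spot_ids)
    prof = extract_profile(scores, proj, n_bins=40, window=1)["sig"]
    assert np.array_equal(prof.raw, prof.smoothed)


def _profile(values: np.ndarray) -> ScoreProfile:
    n = len(values)
    t = (np.arange(n) + 0.5) / n
    return ScoreProfile("sig", t, values, values, np.ones(n, int), 1)


def test_constant_profile_yields_no_segments():
    assert find_change_segments(_profile(np.full(50, 2.0)), 0.01) == []


def test_piecewise_linear_profile_segments_and_threshold():
    n = 100
    t = (np.arange(n) + 0.5) / n
    v = np.clip((t - 0.2) / 0.4, 0, 1)
    segs = find_change_segments(_profile(v), 0.5)
    assert len(segs) == 1
    (seg,) = segs
    assert seg.t0 == pytest.approx(0.2, abs=0.011)
    assert seg.t1 == pytest.approx(0.6, abs=0.011)
    assert seg.slope == pytest.approx(2.5, abs=0.15)
    assert find_change_segments(_profile(v), 3.0) == []


def _seg(sig, t0, t1, v0, v1):
    return ChangeSegment(sig, t0, t1, v0, v1)


def test_pairing_overlap_arithmetic():
    a = _seg("x", 0.1, 0.4, 0.0, 1.0)
    b = _seg("y", 0.3, 0.6, 0.0, 1.0)
    (pair,) = pair_changes([a, b])
    assert pair.overlap == pytest.approx((0.3, 0.4))
    assert pair.overlap_length == pytest.approx(0.1)


def test_disjoint_and_touching_intervals_do_not_pair():
    assert pair_changes([_seg("x", 0.1, 0.2, 0, 1), _seg("y", 0.5, 0.6, 0, 1)]) == []
    assert pair_changes([_seg("x", 0.1, 0.3, 0, 1), _seg("y", 0.3, 0.5, 0, 1)]) == []


def test_same_feature_segments_do_not_pair():
    assert pair_changes([_seg("x", 0.1, 0.4, 0, 1), _seg("x", 0.2, 0.5, 0, 1)]) == []


def test_cor_st_printed_example_and_sign_rule():
    assert cor_st(0.026, 0.028) == pytest.approx(0.054)
    assert cor_st(0.03, -0.02) == pytest.approx(-0.05)
    assert cor_st(-0.03, -0.02) == pytest.approx(0.05)


@settings(deadline=None, derandomize=True)
@given(
    sx=st.floats(-0.1, 0.1).filter(lambda v: abs(v) >= 0.01),
    sy=st.floats(-0.1, 0.1).filter(lambda v: abs(v) >= 0.01),
)
def test_cor_st_contract(sx, sy):
    v = cor_st(sx, sy)
    assert abs(v) == pytest.approx(abs(sx) + abs(sy))
    assert (v > 0) == (np.sign(sx) == np.sign(sy))
    assert cor_st(sy, sx) == pytest.approx(v)


def test_reversing_cluster_order_negates_slopes(small_grid):
    rng = np.random.default_rng(4)
    scores = pd.DataFrame(
        {"sig": small_grid.positions_px[:, 0] / 700.0 + rng.normal(0, 0.01, small_grid.n_spots)},
        index=small_grid.spot_ids,
    )
    fwd_path = build_trajectory(small_grid, ["left", "right"])
    rev_path = build_trajectory(small_grid, ["right", "left"])
    out = {}
    for name, path in (("fwd", fwd_path), ("rev", rev_path)):
        proj = project_spots(path, small_grid, corridor_width=1e6)
        prof = extract_profile(scores, proj, n_bins=8, window=1)["sig"]
        out[name] = find_change_segments(prof, 0.01)
    slopes_f = sorted(s.slope for s in out["fwd"])
    slopes_r = sorted(-s.slope for s in out["rev"])
    assert np.allclose(slopes_f, slopes_r, atol=1e-9)


def test_aggregate_sign_consistency_rule():
    up_x = _seg("x", 0.1, 0.5, 0.0, 1.0)
    up_y = _seg("y", 0.2, 0.6, 0.0, 1.0)
    down_y = _seg("y", 0.2, 0.6, 1.0, 0.0)
    pairs_a = pair_changes([up_x, up_y])
    pairs_b = pair_changes([up_x, down_y])
    full, summary = aggregate_pairs({"A": pairs_a, "B": pairs_b})
    row = summary.set_index(["feature_x", "feature_y"]).loc[("x", "y")]
    assert not row["consistent"]
    assert row["cor_st_sum"] == pytest.approx(
        full["cor_st"].sum()
    )
    _, summary_single = aggregate_pairs({"A": pairs_a})
    assert summary_single["consistent"].all()
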