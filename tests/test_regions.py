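import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from tmeland.grid import SpotGrid, full_lattice, hex_distance
from tmeland.normalize import log_normalize
from tmeland.regions import (
    EnrichmentField,
    RegionError,
    compare_section_maxima,
    deg_wilcoxon,
    enrichment_threshold,
    extract_regions,
    local_enrichment,
)
from tmeland.scoring import SpotLabeling


def _labeling(grid, invasive_ids):
    labels = pd.Series("unassigned", index=grid.spot_ids)
    labels.loc[invasive_ids] = "invasive"
    return SpotLabeling(
        labels=labels,
        winning_score=pd.Series(0.0, index=grid.spot_ids),
        min_score=2.0,
    )


@pytest.fixture()
def lattice_grid():
    return SpotGrid(full_lattice(11, 11))


def test_single_target_kernel_footprint(lattice_grid):
    """One isolated target spot deposits exactly the ring weights."""
    rc = lattice_grid.array_coords
    center = lattice_grid.spot_ids[(rc[:, 0] == 4) & (rc[:, 1] == 10)][0]
    field = local_enrichment(
        lattice_grid, _labeling(lattice_grid, [center]), "invasive",
        radius=2, weights=(3.0, 2.0, 1.0),
    )
    d = hex_distance(4, 10, rc[:, 0], rc[:, 1])
    expected = np.select([d == 0, d == 1, d == 2], [3.0, 2.0, 1.0], default=0.0)
    assert np.array_equal(field.scores.to_numpy(), expected)
    assert (field.scores[d > 2] == 0).all()


def test_enrichment_is_additive_over_targets(lattice_grid):
    """Field of two targets equals the sum of the singleton fields; two
    adjacent targets each score 3 + 2 = 5 under the (3,2,1) kernel."""
    rc = lattice_grid.array_coords
    a = lattice_grid.spot_ids[(rc[:, 0] == 5) & (rc[:, 1] == 9)][0]
    b = lattice_grid.spot_ids[(rc[:, 0] == 5) & (rc[:, 1] == 11)][0]
    kw = dict(radius=2, weights=(3.0, 2.0, 1.0))
    both = local_enrichment(lattice_grid, _labeling(lattice_grid, [a, b]), "invasive", **kw)
    fa = local_enrichment(lattice_grid, _labeling(lattice_grid, [a]), "invasive", **kw)
    fb = local_enrichment(lattice_grid, _labeling(lattice_grid, [b]), "invasive", **kw)
    assert np.allclose(both.scores, fa.scores + fb.scores)
    assert both.scores.loc[a] == 5.0
    assert both.scores.loc[b] == 5.0


def test_weights_must_strictly_decrease(lattice_grid):
    with pytest.raises(RegionError):
        local_enrichment(
            lattice_grid, _labeling(lattice_grid, []), "invasive",
            radius=2, weights=(3.0, 3.0, 1.0),
        )


def _field(values, grid):
    return EnrichmentField(
        scores=pd.Series(values, index=grid.spot_ids[: len(values)]),
        target_class="invasive",
        radius=2,
        weights=(3.0, 2.0, 1.0),
    )


def test_threshold_rule(lattice_grid):
    assert enrichment_threshold(_field([20.0, 0.0], lattice_grid)) == pytest.approx(14.0)
    assert enrichment_threshold(_field([12.0, 0.0], lattice_grid)) == pytest.approx(10.0)
    # boundary: 0.7 × (10/0.7) is not "less than 10"
    assert enrichment_threshold(_field([10.0 / 0.7, 0.0], lattice_grid)) == pytest.approx(10.0)


def test_all_zero_field_warns_and_floors(lattice_grid):
    with pytest.warns(UserWarning, match="all-zero"):
        thr = enrichment_threshold(_field([0.0, 0.0], lattice_grid))
    assert thr == 10.0


def _component_grid_and_field(n_above: int):
    """A straight run of n_above spots scoring 20 on a 3×40 lattice."""
    grid = SpotGrid(full_lattice(3, 40))
    t = grid.table
    scores = pd.Series(0.0, index=grid.spot_ids)
    run = t.index[(t["array_row"] == 1)][:n_above]
    scores.loc[run] = 20.0
    field = EnrichmentField(scores, "invasive", 2, (3.0, 2.0, 1.0))
    return grid, field


@pytest.mark.parametrize("n_above,n_regions", [(15, 0), (16, 1)])
def test_region_size_strictly_more_than_15(n_above, n_regions):
    grid, field = _component_grid_and_field(n_above)
    regions = extract_regions(grid, field, threshold=10.0, min_region_spots=15)
    assert len(regions) == n_regions
    if n_regions:
        assert regions[0].size == 16
        assert regions[0].label == "possibly malignant-invasive"


def test_score_threshold_is_strict():
    grid, field = _component_grid_and_field(20)
    # scores equal to the threshold do not pass
    assert extract_regions(grid, field, threshold=20.0, min_region_spots=1) == []


def test_raising_threshold_is_monotone():
    grid = SpotGrid(full_lattice(8, 8))
    rng = np.random.default_rng(0)
    field = EnrichmentField(
        pd.Series(rng.uniform(0, 30, grid.n_spots), index=grid.spot_ids),
        "invasive", 2, (3.0, 2.0, 1.0),
    )
    prev_total = None
    for thr in (5.0, 10.0, 15.0, 20.0):
        regions = extract_regions(grid, field, thr, min_region_spots=2)
        total = sum(r.size for r in regions)
        if prev_total is not None:
            assert total <= prev_total
        prev_total = total


def test_log_normalize_formula_and_invariance():
    counts = pd.DataFrame([[10, 90]], index=["s"], columns=["g1", "g2"])
    norm = log_normalize(counts, scale=1e4)
    assert norm.iloc[0, 0] == pytest.approx(np.log(1 + 1000))
    assert norm.iloc[0, 1] == pytest.approx(np.log(1 + 9000))
    zero = pd.DataFrame(np.zeros((3, 2)), columns=["g1", "g2"])
    assert (log_normalize(zero) == 0).all().all()
    rng = np.random.default_rng(1)
    counts2 = pd.DataFrame(rng.integers(0, 20, (4, 5)))
    doubled = counts2.copy()
    doubled.iloc[2] *= 2
    pd.testing.assert_series_equal(
        log_normalize(counts2).iloc[2], log_normalize(doubled).iloc[2]
    )


def rank_sum_oracle(x, y):
    """Exhaustive permutation null of the rank-sum statistic (doubled
    smaller tail), coded independently."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    k = len(x)
    obs = ranks[:k].sum()
    stats = [
        sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), k)
    ]
    stats = np.array(stats)
    p = 2 * min((stats <= obs).mean(), (stats >= obs).mean())
    return min(1.0, p)


def test_small_n_pvalues_match_exact_enumeration():
    rng = np.random.default_rng(7)
    genes = {f"g{i}": rng.normal(size=10) for i in range(6)}
    norm = pd.DataFrame(genes, index=[f"s{i}" for i in range(10)])
    mask = pd.Series([True] * 5 + [False] * 5, index=norm.index)
    res = deg_wilcoxon(norm, mask)
    for g in genes:
        expected = rank_sum_oracle(norm[g][mask].to_numpy(), norm[g][~mask].to_numpy())
        assert res.loc[g, "p"] == pytest.approx(expected, abs=1e-10)


def test_identical_groups_give_null_results():
    base = pd.DataFrame(
        np.tile(np.random.default_rng(0).uniform(1, 5, (5, 4)), (2, 1)),
        index=[f"s{i}" for i in range(10)],
        columns=[f"g{i}" for i in range(4)],
    )
    mask = pd.Series([True] * 5 + [False] * 5, index=base.index)
    res = deg_wilcoxon(base, mask)
    assert np.allclose(res["log2fc"], 0.0)
    assert np.allclose(res["p"], 1.0)


def test_planted_gene_is_top_hit():
    rng = np.random.default_rng(11)
    counts = rng.poisson(5.0, size=(200, 50))
    counts[:100, 7] *= 4
    df = pd.DataFrame(
        counts, index=[f"s{i}" for i in range(200)],
        columns=[f"g{i}" for i in range(50)],
    )
    norm = log_normalize(df)
    mask = pd.Series([True] * 100 + [False] * 100, index=df.index)
    res = deg_wilcoxon(norm, mask)
    assert res["log2fc"].abs().idxmax() == "g7"
    assert res.loc["g7", "p_adj"] < 0.01


def test_group_size_minimum_enforced():
    norm = pd.DataFrame(np.ones((5, 2)), columns=["g1", "g2"])
    with pytest.raises(RegionError, match=">= 3"):
        deg_wilcoxon(norm, pd.Series([True, True, False, False, False], index=norm.index))


def test_section_maxima_comparison_exact_and_symmetric():
    maxima = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                       index=[f"sec{i}" for i in range(6)])
    groups = pd.Series(["early"] * 3 + ["invasive"] * 3, index=maxima.index)
    p = compare_section_maxima(maxima, groups)
    assert p == pytest.approx(rank_sum_oracle(maxima[:3].to_numpy(), maxima[3:].to_numpy()), abs=1e-12)
    assert p == pytest.approx(0.1)
    swapped = groups.map({"early": "invasive", "invasive": "early"})
    assert compare_section_maxima(maxima, swapped) == pytest.approx(p)
    with pytest.raises(RegionError):
        compare_section_maxima(maxima[:3], groups[:3])
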