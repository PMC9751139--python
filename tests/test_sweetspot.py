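import numpy as np
import pytest
from scipy import stats as sps

from stimmap.efield import mirror_efield
from stimmap.sweetspot import (
    clusters_to_frame,
    extract_clusters,
    fit_sweetspot,
    score_efield_map,
    SweetspotMap,
)
from stimmap.efield import CoverageMask
from tests.conftest import make_field


def _cohort(small_grid, rng, n=10, lift=0.3):
    fields = [make_field(small_grid, rng.random((5, 5, 5)) + lift, f"p{i}")
              for i in range(n)]
    y = rng.normal(size=n)
    return fields, y


def _map_from(small_grid, values):
    grid = small_grid.like(np.asarray(values, dtype=float))
    mask = CoverageMask(small_grid.like(np.isfinite(values)), 0.2, 0.2)
    return SweetspotMap(grid, mask, 0.2, 0.2, False)


class TestFitSweetspot:
    def test_constant_outcomes_all_nan(self, small_grid, rng):
        fields, _ = _cohort(small_grid, rng)
        smap = fit_sweetspot(fields, np.full(10, 5.0), e_thr=0.2, coverage_fraction=0.2)
        assert np.isnan(smap.values[np.isfinite(smap.values)]).size == 0
        # mask voxels exist but correlations undefined -> NaN everywhere
        assert np.isnan(smap.values).all()

    def test_monotone_voxel_perfect_r(self, small_grid, rng):
        fields, y = _cohort(small_grid, rng)
        order = np.argsort(y)
        for rank, i in enumerate(order):
            fields[i].values[2, 2, 2] = 0.5 + 0.05 * rank
        smap = fit_sweetspot(fields, y, e_thr=0.2, coverage_fraction=0.2)
        assert smap.values[2, 2, 2] == pytest.approx(1.0)

    def test_brute_force_oracle(self, small_grid, rng):
        fields, y = _cohort(small_grid, rng, n=15)
        smap = fit_sweetspot(fields, y, e_thr=0.5, coverage_fraction=0.4)
        stack = np.stack([f.values for f in fields])
        mask = np.isfinite(smap.values)
        assert mask.any()
        for idx in np.argwhere(mask):
            i, j, k = idx
            rho = sps.spearmanr(stack[:, i, j, k], y).statistic
            assert smap.values[i, j, k] == pytest.approx(rho, abs=1e-12)
        # outside mask all NaN
        assert np.isnan(smap.values[~mask]).all()

    def test_mirror_equivariance(self, small_grid, rng):
        fields, y = _cohort(small_grid, rng)
        a = fit_sweetspot(fields, y, e_thr=0.5, coverage_fraction=0.3)
        b = fit_sweetspot([mirror_efield(f) for f in fields], y,
                          e_thr=0.5, coverage_fraction=0.3)
        assert np.array_equal(a.values[::-1], b.values, equal_nan=True)

    def test_mirrored_fit_is_symmetric(self, small_grid, rng):
        fields, y = _cohort(small_grid, rng)
        smap = fit_sweetspot(fields, y, e_thr=0.5, coverage_fraction=0.3,
                             mirrored=True)
        assert np.array_equal(smap.values, smap.values[::-1], equal_nan=True)

    def test_too_few_fields(self, small_grid, rng):
        fields, y = _cohort(small_grid, rng, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            fit_sweetspot(fields, y[:2])


class TestScoreMap:
    def test_zero_field_scores_zero(self, small_grid):
        vals = np.full((5, 5, 5), np.nan)
        vals[1, 1, 1] = 0.8
        smap = _map_from(small_grid, vals)
        E = make_field(small_grid, np.zeros((5, 5, 5)))
        assert score_efield_map(smap, E) == 0.0

    def test_constant_case(self, small_grid):
        vals = np.full((5, 5, 5), np.nan)
        vals[1:3, 1, 1] = 1.0
        smap = _map_from(small_grid, vals)
        E = make_field(small_grid, np.full((5, 5, 5), 0.42))
        assert score_efield_map(smap, E) == pytest.approx(0.42)

    def test_masked_mean_oracle(self, small_grid, rng):
        vals = np.full((5, 5, 5), np.nan)
        sel = rng.random((5, 5, 5)) < 0.4
        vals[sel] = rng.normal(size=sel.sum())
        smap = _map_from(small_grid, vals)
        E = make_field(small_grid, rng.random((5, 5, 5)))
        expect = np.mean([E.values[tuple(i)] * vals[tuple(i)]
                          for i in np.argwhere(sel)])
        assert score_efield_map(smap, E) == pytest.approx(expect, abs=1e-12)

    def test_empty_mask_rejected(self, small_grid, random_field):
        smap = _map_from(small_grid, np.full((5, 5, 5), np.nan))
        with pytest.raises(ValueError, match="no masked voxels"):
            score_efield_map(smap, random_field)


def _flood_fill(binary, conn26=True):
    """Brute-force connected components for the oracle."""
    shape = binary.shape
    labels = np.zeros(shape, dtype=int)
    nxt = 0
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
            and (conn26 or abs(i) + abs(j) + abs(k) == 1)]
    for start in np.argwhere(binary):
        if labels[tuple(start)]:
            continue
        nxt += 1
        stack = [tuple(start)]
        labels[tuple(start)] = nxt
        while stack:
            cur = stack.pop()
            for o in offs:
                nb = tuple(np.array(cur) + o)
                if all(0 <= nb[d] < shape[d] for d in range(3)) \
                        and binary[nb] and not labels[nb]:
                    labels[nb] = nxt
                    stack.append(nb)
    return labels, nxt


class TestClusters:
    def test_single_positive_voxel(self, small_grid):
        vals = np.full((5, 5, 5), np.nan)
        vals[3, 2, 2] = 0.9
        recs = extract_clusters(_map_from(small_grid, vals))
        assert len(recs) == 1
        rec = recs[0]
        assert rec.sign == "sweet" and rec.n_voxels == 1
        world = small_grid.voxel_to_world(np.array([3, 2, 2]))
        assert rec.peak_mm == pytest.approx(world)
        assert rec.cog_mm == pytest.approx(world)

    def test_two_disjoint_blobs(self, small_grid):
        vals = np.full((5, 5, 5), np.nan)
        vals[3, 0, 0] = 0.5
        vals[3, 4, 4] = 0.7
        recs = extract_clusters(_map_from(small_grid, vals))
        assert len([r for r in recs if r.sign == "sweet"]) == 2

    def test_hemisphere_split(self, small_grid):
        vals = np.full((5, 5, 5), np.nan)
        vals[:, 2, 2] = 0.5  # a rod crossing the midline
        recs = extract_clusters(_map_from(small_grid, vals))
        assert {r.hemisphere for r in recs} == {"left", "right"}

    def test_sour_sign(self, small_grid):
        vals = np.full((5, 5, 5), np.nan)
        vals[3, 1, 1] = -0.6
        recs = extract_clusters(_map_from(small_grid, vals))
        assert recs[0].sign == "sour"
        assert recs[0].peak_r == pytest.approx(-0.6)

    def test_flood_fill_oracle(self, small_grid, rng):
        vals = np.full((5, 5, 5), np.nan)
        sel = rng.random((5, 5, 5)) < 0.35
        vals[sel] = rng.uniform(0.1, 1.0, sel.sum())  # all positive
        world = small_grid.world_coordinates()
        right = world[..., 0] >= 0
        recs = extract_clusters(_map_from(small_grid, vals))
        # oracle per hemisphere
        n_expected = 0
        for hemi in (world[..., 0] < 0, right):
            labels, n = _flood_fill(np.nan_to_num(vals) > 0, conn26=True)
            labels = np.where(hemi, labels, 0)
            n_expected += len(set(labels[labels > 0].ravel()))
        assert len(recs) == n_expected
        # peak invariant: |peak| >= any member |R|
        for rec in recs:
            assert abs(rec.peak_r) <= 1.0

    def test_weighted_cog_inside_bbox(self, small_grid, rng):
        vals = np.full((5, 5, 5), np.nan)
        vals[3:5, 1:4, 1:4] = rng.uniform(0.1, 1, (2, 3, 3))
        recs = extract_clusters(_map_from(small_grid, vals))
        world = small_grid.world_coordinates()
        sel = np.isfinite(vals)
        lo, hi = world[sel].min(axis=0), world[sel].max(axis=0)
        for rec in recs:
            assert np.all(rec.cog_mm >= lo - 1e-9) and np.all(rec.cog_mm <= hi + 1e-9)

    def test_frame_columns(self, small_grid):
        vals = np.full((5, 5, 5), np.nan)
        vals[3, 2, 2] = 0.9
        df = clusters_to_frame(extract_clusters(_map_from(small_grid, vals)))
        assert list(df.columns) == ["sign", "hemisphere", "peak_x", "peak_y",
                                    "peak_z", "peak_R", "cog_x", "cog_y",
                                    "cog_z", "n_voxels"]

    def test_empty_map_rejected(self, small_grid):
        with pytest.raises(ValueError, match="empty map"):
            extract_clusters(_map_from(small_grid, np.full((5, 5, 5), np.nan)))
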