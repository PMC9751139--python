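import numpy as np
import pytest
from scipy import stats as sps

from stimmap.data_model import Tractogram
from stimmap.fiber_filtering import (
    filter_fibers,
    fit_fiber_model,
    connected_fibers,
    peak_weights,
    resample_streamline,
    score_weights,
    score_weight_rows,
    weight_matrix,
)
from tests.conftest import make_field


def _line(p0, p1, n=10):
    t = np.linspace(0, 1, n)[:, None]
    return (1 - t) * np.asarray(p0, float) + t * np.asarray(p1, float)


class TestPeakWeights:
    def test_zero_field_zero_weights(self, small_grid):
        E = make_field(small_grid, np.zeros((5, 5, 5)))
        tract = Tractogram([_line((-4, 0, 0), (4, 0, 0))])
        assert peak_weights(E, tract) == pytest.approx([0.0])

    def test_single_hot_voxel(self, small_grid):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 0.7  # world (0,0,0)
        E = make_field(small_grid, vals)
        tract = Tractogram([_line((-4, 0, 0), (4, 0, 0))])
        assert peak_weights(E, tract) == pytest.approx([0.7])

    def test_outside_grid_contributes_zero(self, small_grid):
        E = make_field(small_grid, np.ones((5, 5, 5)))
        tract = Tractogram([_line((50, 50, 50), (60, 60, 60))])
        assert peak_weights(E, tract) == pytest.approx([0.0])

    def test_exhaustive_lookup_oracle(self, small_grid, rng):
        E = make_field(small_grid, rng.random((5, 5, 5)))
        sls = [rng.uniform(-6, 6, (rng.integers(2, 8), 3)) for _ in range(50)]
        tract = Tractogram(sls)
        got = peak_weights(E, tract, step=0.5)
        for f, sl in enumerate(sls):
            pts = resample_streamline(sl, 0.5)
            best = 0.0
            for p in pts:
                ijk, inside = E.grid.world_to_voxel(p)
                if inside:
                    best = max(best, E.values[tuple(ijk)])
            assert got[f] == pytest.approx(best, abs=1e-12)

    def test_empty_tractogram_rejected(self, random_field):
        with pytest.raises(ValueError, match="empty tractogram"):
            peak_weights(random_field, Tractogram([]))

    def test_weight_matrix_matches_per_field(self, small_grid, rng):
        fields = [make_field(small_grid, rng.random((5, 5, 5))) for _ in range(4)]
        tract = Tractogram([rng.uniform(-5, 5, (5, 3)) for _ in range(12)])
        W = weight_matrix(fields, tract)
        for i, E in enumerate(fields):
            assert np.allclose(W[i], peak_weights(E, tract), atol=1e-12)


class TestResample:
    def test_step_bound(self, rng):
        sl = rng.uniform(-10, 10, (6, 3))
        out = resample_streamline(sl, 0.5)
        seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert seg.max() <= 0.5 + 1e-9
        assert np.allclose(out[0], sl[0]) and np.allclose(out[-1], sl[-1])


class TestFilterFibers:
    def test_never_exceeded_excluded(self):
        W = np.zeros((5, 3))
        assert not filter_fibers(W, 0.36, 0.2).any()

    def test_paper_cohort_rule(self):
        # N=28 rows, one fiber over threshold in 6 rows (21.4%) -> included
        W = np.zeros((28, 2))
        W[:6, 0] = 0.4
        W[:5, 1] = 0.4  # 17.9% -> excluded
        inc = filter_fibers(W, e_thr=0.36, coverage_fraction=0.20)
        assert inc.tolist() == [True, False]

    def test_counting_oracle(self, rng):
        W = rng.random((15, 40))
        inc = filter_fibers(W, 0.5, 0.3)
        expect = [(W[:, j] >= 0.5).sum() / 15 >= 0.3 for j in range(40)]
        assert inc.tolist() == expect


class TestFitFiberModel:
    def test_constant_outcomes_gives_empty_model(self, rng):
        W = rng.random((6, 10)) + 0.5
        model = fit_fiber_model(W, np.full(6, 3.0), e_thr=0.1)
        assert model.n_included == 0
        assert np.isnan(model.r).all()

    def test_perfect_monotone_fiber(self):
        W = np.array([[1.0], [2.0], [3.0], [4.0]])
        model = fit_fiber_model(W, np.array([10.0, 20, 30, 40]),
                                e_thr=0.5, coverage_fraction=0.2)
        assert model.r[0] == pytest.approx(1.0)

    def test_against_scipy_oracle(self, rng):
        W = rng.random((20, 30)) + 0.2
        y = rng.normal(size=20)
        model = fit_fiber_model(W, y, e_thr=0.0 + 1e-9, coverage_fraction=0.0 + 1e-9)
        for j in range(30):
            rho = sps.spearmanr(W[:, j], y).statistic
            assert model.r[j] == pytest.approx(rho, abs=1e-12)

    def test_zero_variance_fiber_excluded(self, rng):
        W = rng.random((8, 2)) + 0.5
        W[:, 1] = 0.7
        model = fit_fiber_model(W, rng.normal(size=8), e_thr=0.1)
        assert model.included[0] and not model.included[1]

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="align"):
            fit_fiber_model(rng.random((5, 3)), np.zeros(4))

    def test_rank_invariance_under_monotone_transform(self, rng):
        W = rng.random((12, 20)) + 0.1
        y = rng.normal(size=12)
        m1 = fit_fiber_model(W, y, e_thr=0.0 + 1e-12, coverage_fraction=1e-12)
        m2 = fit_fiber_model(np.exp(3 * W), y, e_thr=np.exp(3e-12),
                             coverage_fraction=1e-12)
        assert np.allclose(m1.r, m2.r, atol=1e-12, equal_nan=True)

    def test_serialization_round_trip(self, rng):
        W = rng.random((10, 8)) + 0.3
        model = fit_fiber_model(W, rng.normal(size=10), e_thr=0.4)
        from stimmap.fiber_filtering import FiberScoreModel
        back = FiberScoreModel.from_dict(model.to_dict())
        assert np.allclose(back.r, model.r, equal_nan=True)
        assert np.array_equal(back.included, model.included)


class TestScore:
    def _model(self, rng, n=20):
        W = rng.random((15, n)) + 0.2
        y = rng.normal(size=15)
        return fit_fiber_model(W, y, e_thr=1e-9, coverage_fraction=1e-9), W

    def test_monotone_transform_of_r_scores_one(self, rng):
        model, _ = self._model(rng)
        w = np.exp(model.r)  # strictly increasing transform
        assert score_weights(model, w) == pytest.approx(1.0)

    def test_antimonotone_scores_minus_one(self, rng):
        model, _ = self._model(rng)
        assert score_weights(model, -model.r) == pytest.approx(-1.0)

    def test_oracle(self, rng):
        model, _ = self._model(rng)
        w = rng.random(model.r.shape[0])
        expect = sps.spearmanr(w[model.included], model.r[model.included]).statistic
        assert score_weights(model, w) == pytest.approx(expect, abs=1e-12)

    def test_score_rows_vectorised(self, rng):
        model, W = self._model(rng)
        rows = score_weight_rows(model, W)
        for i in range(W.shape[0]):
            assert rows[i] == pytest.approx(score_weights(model, W[i]), abs=1e-12)

    def test_too_few_fibers_rejected(self, rng):
        model, _ = self._model(rng, n=20)
        model.included[:] = False
        model.included[0] = True
        with pytest.raises(ValueError, match="too few"):
            score_weights(model, np.ones(20))


class TestConnectedFibers:
    def test_zero_field_empty(self, small_grid, rng):
        tract = Tractogram([rng.uniform(-4, 4, (5, 3)) for _ in range(6)])
        W = rng.random((5, 6)) + 0.3
        model = fit_fiber_model(W, rng.normal(size=5), e_thr=1e-9,
                                coverage_fraction=1e-9)
        E = make_field(small_grid, np.zeros((5, 5, 5)))
        assert connected_fibers(model, E, tract).size == 0

    def test_degenerate_threshold_returns_overlapping(self, small_grid, rng):
        tract = Tractogram([_line((-4, 0, 0), (4, 0, 0)),
                            _line((50, 50, 50), (60, 60, 60))])
        W = rng.random((5, 2)) + 0.3
        model = fit_fiber_model(W, rng.normal(size=5), e_thr=1e-9,
                                coverage_fraction=1e-9)
        E = make_field(small_grid, np.ones((5, 5, 5)))
        assert connected_fibers(model, E, tract, e_thr=0.0).tolist() == [0]


class TestPermutationSensitivity:
    def test_shuffled_outcomes_decorrelate_profile(self, rng):
        from stimmap import synthetic as syn
        from stimmap.fiber_filtering import weight_matrix

        cspec = syn.CohortSpec(n_patients=30)
        table, fields, _ = syn.generate_cohort(cspec, seed=7)
        tract, _ = syn.generate_tractogram(
            syn.TractogramSpec(n_bundles=4, fibers_per_bundle=20), seed=7)
        W = weight_matrix(fields, tract)
        y = table.improvements
        m0 = fit_fiber_model(W, y, e_thr=0.02)
        m1 = fit_fiber_model(W, rng.permutation(y), e_thr=0.02)
        both = m0.included & m1.included
        assert both.sum() >= 10
        rho = sps.spearmanr(m0.r[both], m1.r[both]).statistic
        assert abs(rho) < 0.5
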