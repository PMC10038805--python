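import numpy as np
import pandas as pd
import pytest

import braincast as bc
from braincast.errors import InvalidCurveError, InvalidInputError
from braincast.forecast import ForecastCurve
from conftest import planted_table


def _min_included_offset(stimulus, acts, d, w):
    """Measure the smallest relative word offset present in a window by
    matching its blocks back against the activation rows."""
    window = bc.build_forecast_window(acts, stimulus, d, w)
    M, U = acts.shape
    n = M // 2  # a middle word, away from story edges
    offsets = []
    for j in range(w):
        block = window.values[n, j * U : (j + 1) * U]
        matches = np.nonzero((acts == block).all(axis=1))[0]
        assert len(matches) == 1
        offsets.append(int(matches[0]) - n)
    return min(offsets)


class TestBuildForecastWindow:
    def test_window_contents_by_direct_lookup(self, tiny_stimulus, tiny_activations):
        X = tiny_activations[1]
        M, U = X.shape
        story = tiny_stimulus.story_index()
        rng = np.random.default_rng(0)
        for d, w in [(10, 7), (-3, 4), (0, 1), (5, 2)]:
            window = bc.build_forecast_window(X, tiny_stimulus, d, w)
            assert window.values.shape == (M, w * U)
            for n in rng.integers(0, M, size=12):
                for j in range(w):
                    src = n + d - w + 1 + j
                    block = window.values[n, j * U : (j + 1) * U]
                    if 0 <= src < M and story[src] == story[n]:
                        assert np.array_equal(block, X[src])
                    else:
                        assert np.all(block == 0)

    def test_distance_ten_window_spans_offsets_four_to_ten(self, tiny_stimulus, tiny_activations):
        X = tiny_activations[0]
        assert _min_included_offset(tiny_stimulus, X, d=10, w=7) == 4

    def test_distance_eight_window_spans_offsets_two_to_eight(self, tiny_stimulus, tiny_activations):
        X = tiny_activations[0]
        assert _min_included_offset(tiny_stimulus, X, d=8, w=7) == 2

    def test_zero_distance_unit_width_is_identity(self, tiny_stimulus, tiny_activations):
        X = tiny_activations[2]
        window = bc.build_forecast_window(X, tiny_stimulus, 0, 1)
        assert np.array_equal(window.values, X)


class TestForecastScore:
    def test_duplicate_window_adds_nothing(self, small_planted_dataset):
        # appending a copy of X itself carries no new information: the
        # group-mean gain is bounded by a small dimensionality penalty
        data = small_planted_dataset
        X = data["activations"][2]
        window = bc.build_forecast_window(X, data["stimulus"], 0, 1)
        f = bc.forecast_score(X, window, data["stimulus"], data["runs"])
        assert abs(float(np.nanmean(f.values))) <= 0.01

    def test_random_window_does_not_improve_scores(self, small_planted_dataset):
        data = small_planted_dataset
        X = data["activations"][2]
        rng = np.random.default_rng(9)
        fake = bc.ForecastWindow(
            values=rng.standard_normal((X.shape[0], 4 * X.shape[1])),
            distance=8, width=4,
        )
        f = bc.forecast_score(X, fake, data["stimulus"], data["runs"])
        result = bc.group_significance(f.values, threshold=0.05)
        positive = (result.mask) & (np.nanmean(f.values, axis=0) > 0)
        assert not positive.any()

    def test_planted_distance_beats_baseline_distance(self, small_planted_dataset):
        data = small_planted_dataset
        X = data["activations"][2]
        w10 = bc.build_forecast_window(X, data["stimulus"], 10, 7)
        w0 = bc.build_forecast_window(X, data["stimulus"], 0, 7)
        f10 = bc.forecast_score(X, w10, data["stimulus"], data["runs"])
        f0 = bc.forecast_score(X, w0, data["stimulus"], data["runs"])
        # voxels 2, 3 are planted at distance 10
        diff = (f10.values - f0.values)[:, [2, 3]]
        assert np.mean(diff) > 0.02
        assert (diff.mean(axis=1) > 0).all()  # every subject


def _synthetic_curve(grid, peaks, n_subjects=6, bump=0.3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    V = len(peaks)
    values = np.zeros((n_subjects, V, len(grid)))
    for v, peak in enumerate(peaks):
        if peak is not None:
            values[:, v, :] = bump - 0.01 * np.abs(grid - peak)[None, :]
    values += noise * rng.standard_normal(values.shape)
    return ForecastCurve(values=values, distance_grid=np.asarray(grid, int),
                         subjects=[f"sub-{i}" for i in range(n_subjects)])


class TestDistanceMap:
    def test_unimodal_curve_peaks_at_its_mode(self):
        grid = np.arange(-10, 31)
        curves = _synthetic_curve(grid, peaks=[8] * 8, noise=0.002)
        dmap = bc.forecast_distance_map(curves, bc.ForecastConfig())
        assert np.all(np.abs(dmap.dstar - 8) <= 1)

    def test_flat_curve_ties_to_smallest_distance_and_is_masked(self):
        grid = np.arange(-10, 31)
        curves = _synthetic_curve(grid, peaks=[None] * 6)
        with pytest.warns(RuntimeWarning, match="all-zero"):
            dmap = bc.forecast_distance_map(curves, bc.ForecastConfig())
        assert np.all(dmap.dstar == -10)
        assert not dmap.mask.any()
        assert np.all(np.isnan(dmap.group_mean()))

    def test_incomplete_grid_rejected(self):
        curves = _synthetic_curve(np.arange(-2, 12), peaks=[5] * 6)
        with pytest.raises(InvalidCurveError):
            bc.forecast_distance_map(curves, bc.ForecastConfig())

    def test_recovers_planted_distances_on_synthetic_data(self, small_planted_dataset):
        data = small_planted_dataset
        fc = bc.ForecastConfig(distance_grid=np.arange(-2, 15))
        curves = bc.forecast_curves(
            data["activations"][2], data["stimulus"], data["runs"], fc_config=fc
        )
        dmap = bc.forecast_distance_map(curves, fc)
        mean_d = dmap.dstar.mean(axis=0)
        planted = data["truth"].set_index("voxel_id")["planted_distance"]
        for v, d in planted.items():
            assert abs(mean_d[v] - d) <= 2


class TestDepthMap:
    def test_tie_breaks_toward_shallowest_layer(self):
        subjects = [f"sub-{i}" for i in range(6)]
        scores = {
            k: bc.ScoreMap(values=np.full((6, 3), 0.2), subjects=subjects)
            for k in range(13)
        }
        kmap = bc.forecast_depth_map(scores, bc.ForecastConfig(),
                                     mask=np.zeros(3, bool))
        assert np.all(kmap.kstar == 0)
        assert np.all(np.isnan(kmap.group_mean()))

    def test_missing_layer_rejected(self):
        subjects = [f"sub-{i}" for i in range(6)]
        scores = {
            k: bc.ScoreMap(values=np.zeros((6, 2)), subjects=subjects)
            for k in range(12)
        }
        with pytest.raises(InvalidInputError, match="12"):
            bc.forecast_depth_map(scores, bc.ForecastConfig())

    def test_planted_depth_ordering(self):
        # voxels reading a shallow layer get smaller k* than voxels
        # reading a deep layer, with clear separation
        stim = bc.generate_stimulus(1500, 2.54, 2, seed=31)
        acts = bc.generate_layered_embeddings(stim, 13, dim=4, seed=32)
        plants = planted_table(
            [(v, 8, 2, "full", 5.0) for v in range(3)]
            + [(v, 8, 10, "full", 5.0) for v in range(3, 6)]
        )
        spec = bc.SyntheticSpec(n_subjects=6, n_voxels=6, voxel_plants=plants, seed=33)
        runs, _ = bc.generate_bold(stim, acts, spec)
        scores = bc.forecast_depth_curves(
            {k: acts[k] for k in range(13)}, stim, runs
        )
        kmap = bc.forecast_depth_map(scores, bc.ForecastConfig())
        shallow = kmap.kstar[:, :3].mean()
        deep = kmap.kstar[:, 3:].mean()
        assert shallow <= 4
        assert deep >= shallow + 2
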