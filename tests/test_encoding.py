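import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.preprocessing import StandardScaler

import braincast as bc
from braincast.encoding import cv_fold_correlations, fold_feature_projections
from braincast.errors import InvalidSplitError, ShapeError


class TestContiguousFolds:
    def test_even_split(self):
        folds = bc.contiguous_folds(10, 5)
        assert [list(f) for f in folds] == [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9]]

    def test_remainder_goes_to_front(self):
        folds = bc.contiguous_folds(11, 5)
        assert [len(f) for f in folds] == [3, 2, 2, 2, 2]

    @given(T=st.integers(5, 200), k=st.integers(2, 5))
    def test_partition_property(self, T, k):
        folds = bc.contiguous_folds(T, k)
        flat = np.concatenate(folds)
        assert np.array_equal(flat, np.arange(T))  # contiguous, disjoint, complete
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidSplitError):
            bc.contiguous_folds(3, 5)


class TestFitRidgeCV:
    def test_noiseless_linear_target_uses_least_regularisation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        y = X[:, 0]
        model = bc.fit_ridge_cv(X[:50], y[:50])
        assert model.chosen_lambda[0] == pytest.approx(0.1)
        pred = X[50:] @ model.weights[:, 0]
        r = np.corrcoef(pred, y[50:])[0, 1]
        assert r > 0.999

    def test_pure_noise_targets_score_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 5))
        Y = rng.standard_normal((200, 50))
        model = bc.fit_ridge_cv(X[:150], Y[:150])
        pred = X[150:] @ model.weights
        rs = [np.corrcoef(pred[:, v], Y[150:, v])[0, 1] for v in range(50)]
        assert abs(np.mean(rs)) < 0.1

    def test_loo_errors_match_brute_force_refits(self):
        # 30 x 3 fixed instance: the efficient LOO errors must equal
        # per-left-out-row refits for every penalty in the grid
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 3))
        Y = rng.standard_normal((30, 2))
        grid = np.logspace(-1, 8, 10)
        model = bc.fit_ridge_cv(X, Y, grid, store_loo=True)
        brute = np.empty((30, 2, len(grid)))
        for a, lam in enumerate(grid):
            for i in range(30):
                mask = np.ones(30, bool)
                mask[i] = False
                fit = Ridge(alpha=lam, fit_intercept=False).fit(X[mask], Y[mask])
                brute[i, :, a] = (Y[i] - fit.predict(X[i : i + 1])[0]) ** 2
        assert np.abs(brute - model.loo_errors).max() < 1e-8
        chosen_brute = grid[np.argmin(brute.mean(axis=0), axis=1)]
        assert np.array_equal(chosen_brute, model.chosen_lambda)

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ShapeError):
            bc.fit_ridge_cv(np.ones((5, 2)), np.ones((6, 1)))


def _reference_brain_score(X, Y, n_folds=5, n_components=20, grid=None):
    """Straightforward recomposition of the pipeline: per fold, scaler +
    PCA + per-target LOO ridge fitted on train rows, Pearson r on test."""
    from sklearn.linear_model import RidgeCV

    grid = np.logspace(-1, 8, 10) if grid is None else grid
    T = X.shape[0]
    folds = np.array_split(np.arange(T), n_folds)
    rs = []
    for test in folds:
        train = np.setdiff1d(np.arange(T), test)
        scaler = StandardScaler().fit(X[train])
        Xtr, Xte = scaler.transform(X[train]), scaler.transform(X[test])
        pca = PCA(n_components=min(n_components, Xtr.shape[1]), random_state=0).fit(Xtr)
        Ztr, Zte = pca.transform(Xtr), pca.transform(Xte)
        mean = Y[train].mean(axis=0)
        ridge = RidgeCV(alphas=grid, fit_intercept=False, alpha_per_target=True)
        ridge.fit(Ztr, Y[train] - mean)
        pred = ridge.predict(Zte) + mean
        rs.append(
            [np.corrcoef(pred[:, v], Y[test][:, v])[0, 1] for v in range(Y.shape[1])]
        )
    return np.mean(rs, axis=0)


class TestBrainScore:
    def test_matches_step_by_step_reference(self):
        rng = np.random.default_rng(3)
        T, U, V = 50, 4, 2
        X = rng.standard_normal((T, U))
        Y = X @ rng.standard_normal((U, V)) + 0.5 * rng.standard_normal((T, V))
        run = bc.BoldRun(values=Y, tr=1.5)
        ours = bc.brain_score(X, run).values[0]
        ref = _reference_brain_score(X, Y)
        assert np.allclose(ours, ref, atol=1e-10)

    def test_noiseless_linear_readout_scores_high(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((300, 6))
        Y = X @ rng.standard_normal((6, 3))
        run = bc.BoldRun(values=Y, tr=1.5)
        assert np.all(bc.brain_score(X, run).values >= 0.95)

    def test_scores_invariant_to_affine_feature_rescaling(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 5))
        Y = X @ rng.standard_normal((5, 4)) + rng.standard_normal((120, 4))
        run = bc.BoldRun(values=Y, tr=1.5)
        base = bc.brain_score(X, run).values
        X2 = X.copy()
        X2[:, 0] = 13.0 * X2[:, 0] - 7.0
        rescaled = bc.brain_score(X2, run).values
        assert np.allclose(base, rescaled, atol=1e-8)

    def test_test_fold_bold_never_reaches_the_fit(self):
        # the model evaluated on fold f must be fitted without fold f's
        # BOLD: its predictions are identical whether or not the test
        # fold's BOLD is perturbed, so the fold correlation changes only
        # through the actual values it is compared against
        rng = np.random.default_rng(6)
        X = rng.standard_normal((100, 4))
        Y = X @ rng.standard_normal((4, 3)) + rng.standard_normal((100, 3))
        config = bc.EncodingConfig()
        folds = bc.contiguous_folds(100, config.n_folds)
        proj = fold_feature_projections([X], folds, config)
        base = cv_fold_correlations(proj, folds, Y, config)
        Y2 = Y.copy()
        Y2[folds[2]] = Y2[rng.permutation(folds[2])]
        perturbed = cv_fold_correlations(proj, folds, Y2, config)
        assert not np.allclose(base[2], perturbed[2])
        # reproduce fold 2's perturbed score from the *unperturbed* fit
        train = np.setdiff1d(np.arange(100), folds[2])
        Ztr, Zte = proj[2]
        mean = Y[train].mean(axis=0)
        model = bc.fit_ridge_cv(Ztr, Y[train] - mean, config.lambda_grid)
        pred = Zte @ model.weights + mean
        expected = [
            np.corrcoef(pred[:, v], Y2[folds[2]][:, v])[0, 1] for v in range(3)
        ]
        assert np.allclose(perturbed[2], expected)

    def test_zero_variance_voxel_flagged_nan(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 3))
        Y = np.hstack([X @ rng.standard_normal((3, 1)), np.zeros((50, 1))])
        run = bc.BoldRun(values=Y, tr=1.5)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            scores = bc.brain_score(X, run)
        assert np.isnan(scores.values[0, 1])
        assert np.isfinite(scores.values[0, 0])

    def test_score_does_not_decrease_with_signal_gain(self, tiny_stimulus, tiny_activations):
        from braincast.forecast import _word_block_to_design
        from conftest import planted_table

        means = []
        for gain in (1.0, 3.0, 9.0):
            plants = planted_table([(v, 0, 2, "full", gain) for v in range(6)])
            spec = bc.SyntheticSpec(
                n_subjects=4, n_voxels=6, voxel_plants=plants, seed=21
            )
            runs, _ = bc.generate_bold(tiny_stimulus, tiny_activations, spec)
            design = _word_block_to_design(
                tiny_activations[2], tiny_stimulus, runs[0].tr, runs[0].n_scans, 6
            )
            means.append(float(np.nanmean(bc.brain_score(design, runs).values)))
        assert means[0] < means[1] < means[2]
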