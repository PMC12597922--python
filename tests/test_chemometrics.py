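"""NIPALS/SIMCA/OPLS-DA against SVD and hand-computed oracles."""

import numpy as np
import pytest

from ganoderma_ftir.chemometrics import (
    classify_pca_class,
    dmodx,
    fit_oplsda,
    fit_pca_class,
    fit_pca_nipals,
    permutation_test,
    predict_oplsda,
    q2_cross_validation,
    rmse_estimation,
)


class TestNipalsPca:
    @pytest.mark.parametrize("shape,seed", [((8, 5), 0), ((20, 20), 1), ((12, 7), 2), ((15, 4), 3)])
    def test_matches_svd_oracle_up_to_sign(self, shape, seed):
        x = np.random.default_rng(seed).normal(size=shape)
        n_comp = min(3, shape[1], shape[0] - 1)
        model = fit_pca_nipals(x, n_comp)
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        for a in range(n_comp):
            cosine = abs(float(model.loadings[:, a] @ vt[a]))
            assert cosine == pytest.approx(1.0, abs=1e-6)
            np.testing.assert_allclose(
                np.abs(model.scores[:, a]), np.abs(u[:, a] * s[a]), atol=1e-6
            )

    def test_rank_one_matrix_fully_explained(self):
        t = np.array([1.0, 2.0, -1.0, 0.5])
        p = np.array([0.3, -0.7, 0.2])
        x = np.outer(t, p)
        model = fit_pca_nipals(x, 1)
        assert model.r2x_per_component[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal(self):
        x = np.random.default_rng(4).normal(size=(10, 6))
        model = fit_pca_nipals(x, 4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca_nipals(np.ones((5, 3)), 4)


class TestQ2CrossValidation:
    def test_leave_one_out_matches_hand_oracle(self):
        x = np.array(
            [[1.0, 0.2, 0.0], [2.1, -0.3, 0.4], [-1.2, 0.5, -0.1], [0.3, 1.4, 0.8]]
        )
        result = q2_cross_validation(x, n_folds=4, component_range=[1], seed=0)
        # independent oracle: explicit leave-one-out with SVD-based PCA
        press = ss = 0.0
        for i in range(4):
            train = np.delete(x, i, axis=0)
            mean = train.mean(axis=0)
            _, _, vt = np.linalg.svd(train - mean, full_matrices=False)
            v = vt[0]
            xc = x[i] - mean
            resid = xc - v * (v @ xc)
            press += float(resid @ resid)
            ss += float(xc @ xc)
        assert result[1] == pytest.approx(1 - press / ss, abs=1e-6)

    def test_pure_noise_has_low_q2(self):
        values = []
        for seed in range(6):
            x = np.random.default_rng(seed).normal(size=(20, 12))
            values.append(q2_cross_validation(x, n_folds=5, component_range=[1], seed=seed)[1])
        assert np.mean(values) < 0.2

    def test_noise_free_low_rank_structure_high_q2(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=(30, 2)) * [5.0, 2.0]
        loadings = np.linalg.qr(rng.normal(size=(10, 2)))[0]
        x = scores @ loadings.T
        q2 = q2_cross_validation(x, n_folds=5, component_range=[2], seed=0)[2]
        assert q2 > 0.9


class TestPcaClass:
    @pytest.fixture
    def class_mats(self, small_dataset):
        from ganoderma_ftir.preprocess import run_chain

        processed = run_chain(small_dataset)
        return {
            c: processed.absorbance[processed.labels == c] for c in processed.classes
        }, processed

    def test_thresholds_finite_positive(self, class_mats):
        mats, _ = class_mats
        model = fit_pca_class(mats, alpha=0.05)
        for cls in mats:
            assert np.isfinite(model.dmodx_critical[cls])
            assert model.dmodx_critical[cls] > 0

    def test_calibration_coverage_matches_nominal_level(self):
        # pooled over seeds; nominal coverage at alpha=0.05 is 95%, so the
        # assertion allows one-sided binomial noise (99% bound at ~330 draws)
        from ganoderma_ftir.dataset import WavenumberGrid
        from ganoderma_ftir.preprocess import run_chain
        from ganoderma_ftir.synthetic import generate_dataset
        from tests.conftest import make_small_profiles

        grid = WavenumberGrid(1800, 800, 4)
        hits = total = 0
        for seed in range(3):
            spectra = generate_dataset(
                make_small_profiles((40, 30, 30)), grid,
                baseline_order=1, baseline_scale=0.05, noise_sd=0.005, seed=seed,
            )
            processed = run_chain(spectra)
            mats = {c: processed.absorbance[processed.labels == c] for c in processed.classes}
            model = fit_pca_class(mats)
            for cls, mat in mats.items():
                d = dmodx(model, mat)[cls]
                hits += int(np.sum(d <= model.dmodx_critical[cls]))
                total += mat.shape[0]
        assert hits / total >= 0.95 - 2.33 * np.sqrt(0.95 * 0.05 / total)

    def test_pure_noise_flagged_no_class(self, class_mats):
        mats, processed = class_mats
        model = fit_pca_class(mats)
        noise = np.random.default_rng(8).normal(size=(6, processed.n_points))
        _, _, membership = classify_pca_class(model, noise)
        flags = np.vstack([membership[c] for c in model.class_order])
        assert not flags.any()

    def test_class_centroid_wins(self, class_mats):
        mats, _ = class_mats
        model = fit_pca_class(mats)
        for cls, mat in mats.items():
            labels, _, _ = classify_pca_class(model, mat.mean(axis=0, keepdims=True))
            assert labels[0] == cls

    def test_empty_input_empty_prediction(self, class_mats):
        mats, processed = class_mats
        model = fit_pca_class(mats)
        labels, _, _ = classify_pca_class(model, np.empty((0, processed.n_points)))
        assert labels.size == 0


def _planted_confounder(seed=0, n=40, p=30):
    rng = np.random.default_rng(seed)
    basis = np.linalg.qr(rng.normal(size=(p, 2)))[0]
    v_signal, v_conf = basis[:, 0], basis[:, 1]
    y = np.repeat([1.0, -1.0], n // 2)
    t_conf = rng.normal(scale=3.0, size=n)
    t_conf -= y * (y @ t_conf) / (y @ y)  # empirically Y-orthogonal confounder
    x = np.outer(y, v_signal) + np.outer(t_conf, v_conf) + 0.01 * rng.normal(size=(n, p))
    labels = np.where(y > 0, "pos", "neg")
    return x, labels, v_signal, v_conf


class TestOplsda:
    def test_orthogonal_component_recovers_planted_confounder(self):
        x, labels, _, v_conf = _planted_confounder()
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=1)
        cosine = abs(float(model.orthogonal_weights[:, 0] @ v_conf))
        assert cosine > 0.95

    def test_r2y_near_one_on_noise_free_separable_toy(self):
        rng = np.random.default_rng(1)
        labels = np.asarray(["a"] * 10 + ["b"] * 10 + ["c"] * 10, dtype=object)
        y = np.zeros((30, 3))
        for i, lab in enumerate(labels):
            y[i, ord(lab) - ord("a")] = 1.0
        v = np.linalg.qr(rng.normal(size=(12, 3)))[0]
        x = (y - y.mean(axis=0)) @ v.T  # exact class geometry, no noise
        model = fit_oplsda(x, labels, n_predictive=2, n_orthogonal=0)
        assert model.quality.r2y >= 0.99

    def test_identical_classes_find_nothing(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(24, 15))
        labels = np.asarray(["a", "b"] * 12, dtype=object)
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=0)
        assert model.quality.q2y <= 0.0

    def test_predict_on_training_reproduces_fit_assignments(self, small_dataset):
        from ganoderma_ftir.preprocess import run_chain

        processed = run_chain(small_dataset)
        model = fit_oplsda(processed.absorbance, processed.labels)
        labels, y_pred, _ = predict_oplsda(model, processed.absorbance)
        assert model.quality.accuracy == pytest.approx(
            100.0 * float(np.mean(labels == processed.labels))
        )

    def test_single_spectrum_single_label(self, small_dataset):
        from ganoderma_ftir.preprocess import run_chain

        processed = run_chain(small_dataset)
        model = fit_oplsda(processed.absorbance, processed.labels)
        labels, y_pred, _ = predict_oplsda(model, processed.absorbance[:1])
        assert labels.shape == (1,)
        assert y_pred.shape == (1, 3)

    def test_grid_mismatch_rejected(self, small_dataset):
        model = fit_oplsda(small_dataset.absorbance, small_dataset.labels)
        with pytest.raises(ValueError, match="mismatch"):
            predict_oplsda(model, small_dataset.absorbance[:, :-1])

    def test_score_blocks_uncorrelated(self):
        x, labels, _, _ = _planted_confounder(seed=3)
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=1)
        r = np.corrcoef(model.predictive_scores[:, 0], model.orthogonal_scores[:, 0])[0, 1]
        assert abs(r) < 1e-6

    def test_variance_bookkeeping_sums_to_one(self):
        x, labels, _, _ = _planted_confounder(seed=4)
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=1)
        xc = (x - model.x_means) / model.x_divisors
        recon = (
            model.predictive_scores @ model.predictive_loadings.T
            + model.orthogonal_scores @ model.orthogonal_loadings.T
        )
        resid_frac = float(np.sum((xc - recon) ** 2)) / float(np.sum(xc**2))
        assert model.quality.r2x_predictive + model.quality.r2x_orthogonal + resid_frac == (
            pytest.approx(1.0, abs=1e-8)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_oplsda(np.ones((6, 4)), ["a"] * 6)


class TestPermutationTest:
    def test_reference_metrics_match_direct_fit(self):
        x, labels, _, _ = _planted_confounder(seed=5)
        result = permutation_test(x, labels, n_permutations=5, seed=1, n_orthogonal=0)
        model = fit_oplsda(x, labels, n_predictive=1, n_orthogonal=0, cv_seed=1)
        assert result.r2y_reference == pytest.approx(model.quality.r2y, abs=1e-9)
        assert result.q2y_reference == pytest.approx(model.quality.q2y, abs=1e-9)

    def test_correlations_in_unit_interval_and_seeded(self):
        x, labels, _, _ = _planted_confounder(seed=6)
        a = permutation_test(x, labels, n_permutations=8, seed=2, n_orthogonal=0)
        b = permutation_test(x, labels, n_permutations=8, seed=2, n_orthogonal=0)
        np.testing.assert_array_equal(a.correlations, b.correlations)
        assert np.all(a.correlations >= 0) and np.all(a.correlations <= 1)

    def test_permuted_q2_below_reference_on_separable_data(self):
        x, labels, _, _ = _planted_confounder(seed=7)
        result = permutation_test(x, labels, n_permutations=10, seed=3, n_orthogonal=0)
        assert result.q2y_reference > np.max(result.q2y_values)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones((6, 3)), ["a"] * 6, n_permutations=3, seed=0)


class TestRmseEstimation:
    def test_zero_residuals_all_flavors(self):
        zero = np.zeros(5)
        for flavor in ("RMSEE", "RMSECV", "RMSEP"):
            assert rmse_estimation(zero, n_components=1, flavor=flavor) == 0.0

    def test_rmsep_hand_toy(self):
        assert rmse_estimation(np.array([1.0, -1.0]), flavor="RMSEP") == pytest.approx(1.0)

    def test_rmsee_degrees_of_freedom(self):
        residuals = np.array([0.0, 0.0, 3.0])
        assert rmse_estimation(residuals, n_components=1, flavor="RMSEE") == pytest.approx(3.0)
        with pytest.raises(ValueError):
            rmse_estimation(residuals, n_components=2, flavor="RMSEE")
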