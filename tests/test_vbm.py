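"""Gray-matter-intensity branch: smoothing, age correction, masking, PCA."""
import numpy as np
import pytest

from conftest import make_volume
from levoresp import vbm
from levoresp.grids import VolumeGrid


class TestSmoothing:
    def test_zero_fwhm_identity(self, rng):
        v = make_volume(rng.normal(size=(10, 10, 10)))
        out = vbm.smooth_volume(v, 0.0)
        assert np.array_equal(out.data, v.data)

    def test_constant_volume_unchanged(self):
        v = make_volume(np.full((8, 8, 8), 3.5))
        out = vbm.smooth_volume(v, 8.0)
        assert np.allclose(out.data, 3.5, atol=1e-6)

    def test_delta_impulse_matches_separable_gaussian(self):
        data = np.zeros((31, 31, 31))
        data[15, 15, 15] = 1.0
        fwhm, voxel = 8.0, 2.0
        out = vbm.smooth_volume(make_volume(data, voxel=voxel), fwhm)
        assert out.data.sum() == pytest.approx(1.0, rel=1e-6)
        sigma = fwhm / (voxel * vbm.FWHM_TO_SIGMA)
        peak = (1.0 / (sigma * np.sqrt(2 * np.pi))) ** 3
        assert out.data[15, 15, 15] == pytest.approx(peak, rel=0.02)

    def test_mean_preserved(self, rng):
        v = make_volume(rng.normal(size=(12, 14, 12)))
        out = vbm.smooth_volume(v, 6.0)
        assert out.data.mean() == pytest.approx(v.data.mean(), abs=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            vbm.smooth_volume(make_volume(np.zeros((4, 4, 4))), -1.0)


class TestAgeModel:
    def _trended(self, ages, slope, noise=0.0, rng=None):
        base = np.full((6, 6, 6), 50.0)
        vols = []
        for a in ages:
            d = base + slope * a
            if noise and rng is not None:
                d = d + rng.normal(0, noise, base.shape)
            vols.append(make_volume(d))
        return vols

    def test_noiseless_recovery_exact(self):
        ages = np.linspace(40, 80, 12)
        model = vbm.fit_age_model(self._trended(ages, 0.2), ages)
        assert np.allclose(model.slope, 0.2, atol=1e-5)  # float32 volumes

    def test_age_independent_volumes(self):
        ages = np.linspace(40, 80, 12)
        model = vbm.fit_age_model(self._trended(ages, 0.0), ages)
        assert np.allclose(model.slope, 0.0, atol=1e-6)

    def test_noisy_recovery_within_ols_bound(self, rng):
        ages = rng.uniform(40, 80, 100)
        model = vbm.fit_age_model(self._trended(ages, -0.5, noise=1.0, rng=rng), ages)
        assert abs(model.slope.mean() - (-0.5)) < 0.05

    def test_zero_age_variance_rejected(self):
        ages = np.full(12, 60.0)
        with pytest.raises(ValueError):
            vbm.fit_age_model(self._trended(ages, 0.1), ages)

    def test_correction_removes_age_trend(self, rng):
        ages = rng.uniform(40, 80, 80)
        vols = self._trended(ages, -0.5, noise=1.0, rng=rng)
        model = vbm.fit_age_model(vols, ages)
        corrected = [vbm.age_correct(v, a, model) for v, a in zip(vols, ages)]
        means = np.array([c.data.mean() for c in corrected])
        r = np.corrcoef(ages, means)[0, 1]
        assert abs(r) < 0.05

    def test_correction_identity_cases(self, rng):
        v = make_volume(rng.normal(size=(6, 6, 6)))
        model = vbm.AgeModel(np.zeros((6, 6, 6)), np.zeros((6, 6, 6)), 60.0)
        assert np.allclose(vbm.age_correct(v, 90.0, model).data, v.data)
        model2 = vbm.AgeModel(np.full((6, 6, 6), 0.3), np.zeros((6, 6, 6)), 60.0)
        assert np.allclose(vbm.age_correct(v, 60.0, model2).data, v.data)

    def test_grid_mismatch_rejected(self, rng):
        v = make_volume(rng.normal(size=(6, 6, 6)))
        model = vbm.AgeModel(np.zeros((5, 5, 5)), np.zeros((5, 5, 5)), 60.0)
        with pytest.raises(ValueError):
            vbm.age_correct(v, 70.0, model)


class TestDiscriminativeMask:
    def test_planted_shift_recovers_roi(self, rng):
        shape = (10, 10, 10)
        roi = np.zeros(shape, dtype=bool)
        roi[2:6, 2:6, 2:6] = True
        y = np.array([0, 1] * 100)
        vols = []
        for label in y:
            d = rng.normal(0, 1, shape)
            if label:
                d[roi] += 1.5
            vols.append(make_volume(d))
        mask = vbm.find_discriminative_voxels(vols, y, alpha=0.001)
        assert (mask.mask & roi).sum() > 0.5 * roi.sum()

    def test_null_calibration(self, rng):
        vols = [make_volume(rng.normal(size=(12, 12, 12))) for _ in range(100)]
        y = np.array([0, 1] * 50)
        mask = vbm.find_discriminative_voxels(vols, y, alpha=0.01)
        frac = mask.mask.mean()
        # binomial 99.9% band around alpha for 1728 voxels
        assert frac < 0.01 + 3.3 * np.sqrt(0.01 * 0.99 / 1728)

    def test_alpha_one_selects_everything(self, rng):
        vols = [make_volume(rng.normal(size=(4, 4, 4))) for _ in range(10)]
        y = np.array([0, 1] * 5)
        mask = vbm.find_discriminative_voxels(vols, y, alpha=1.0)
        assert mask.mask.all()

    def test_single_class_rejected(self, rng):
        vols = [make_volume(rng.normal(size=(4, 4, 4))) for _ in range(6)]
        with pytest.raises(ValueError):
            vbm.find_discriminative_voxels(vols, np.ones(6))


class TestPCA:
    def test_rank_deficient_tail_components_vanish(self, rng):
        basis = rng.normal(size=(2, 20))
        X = rng.normal(size=(30, 2)) @ basis
        scores, _, _ = vbm.pca_reduce(X, n_components=6)
        assert scores[:, 2:].var(axis=0).max() < 1e-20

    def test_reconstruction_at_full_rank(self, rng):
        X = rng.normal(size=(10, 6))
        scores, loadings, mean = vbm.pca_reduce(X, n_components=6)
        assert np.allclose(scores @ loadings + mean, X, atol=1e-8)

    def test_component_variance_non_increasing(self, rng):
        X = rng.normal(size=(40, 15))
        scores, _, _ = vbm.pca_reduce(X, n_components=10)
        var = scores.var(axis=0)
        assert np.all(np.diff(var) <= 1e-10)


class TestExtractorLeakage:
    def test_test_labels_never_touch_features(self, small_cohort, rng):
        co = small_cohort
        n_train = 40
        ages = np.array([r.age for r in co.clinical])
        ext = vbm.GrayMatterIntensityExtractor(n_components=5)
        ext.fit(co.volumes[:n_train], ages[:n_train], co.y[:n_train],
                co.healthy_volumes, co.healthy_ages)
        test_vols, test_ages = co.volumes[n_train:], ages[n_train:]
        f1 = ext.transform(test_vols, test_ages)
        # shuffling test labels is irrelevant by construction; features of a
        # permuted test list are the same rows permuted
        perm = rng.permutation(len(test_vols))
        f2 = ext.transform([test_vols[i] for i in perm], test_ages[perm])
        assert np.allclose(f1[perm], f2)
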