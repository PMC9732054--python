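import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import lulcst as L
from lulcst.errors import ArgumentError


def bands_from_cube(cube, pixel_size_m=30.0):
    return [L.BandGrid(values=cube[..., b], pixel_size_m=pixel_size_m)
            for b in range(cube.shape[-1])]


class TestSignatures:
    def test_identical_training_pixels_get_epsilon_identity(self):
        cube = np.zeros((2, 2, 3))
        cube[...] = [10.0, 20.0, 30.0]
        train = pd.DataFrame({"row": [0, 0, 1, 1], "col": [0, 1, 0, 1],
                              "label": [0, 0, 0, 0]})
        cube2 = np.concatenate([cube, cube + 5], axis=0)
        train2 = pd.concat([train, train.assign(row=train.row + 2,
                                                label=1)])
        sigs = L.extract_signatures(bands_from_cube(cube2), train2)
        s0 = sigs[0]
        assert np.allclose(s0.mean, [10, 20, 30])
        assert s0.regularization > 0
        assert np.allclose(s0.covariance,
                           s0.regularization * np.eye(3))

    def test_hand_computed_mean_and_covariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 2))
        cube = np.zeros((1, 5, 2))
        cube[0] = x
        train = pd.DataFrame({"row": [0] * 5, "col": range(5),
                              "label": [0] * 5})
        cube2 = np.concatenate([cube, cube + 100], axis=0)
        train2 = pd.concat([train, train.assign(row=1, label=1)])
        sig = L.extract_signatures(bands_from_cube(cube2), train2)[0]
        assert np.allclose(sig.mean, x.mean(axis=0))
        # n-1 denominator, no regularization needed for this sample
        assert np.allclose(sig.covariance, np.cov(x, rowvar=False, ddof=1))
        assert sig.n_train == 5

    def test_point_on_nodata_pixel_is_skipped(self):
        cube = np.random.default_rng(1).normal(size=(4, 4, 2))
        bands = bands_from_cube(cube)
        bands[0].nodata_mask[0, 0] = True
        train = pd.DataFrame({
            "row": [0, 1, 1, 2, 2, 3, 3, 0], "col": [0, 1, 2, 1, 2, 1, 2, 3],
            "label": [0, 0, 0, 0, 1, 1, 1, 1]})
        sigs = L.extract_signatures(bands, train)
        assert sigs[0].n_train == 3  # the nodata point dropped

    def test_too_few_points_names_class(self):
        cube = np.zeros((2, 3, 2))
        train = pd.DataFrame({"row": [0, 0, 0, 1, 1, 1],
                              "col": [0, 1, 2, 0, 1, 2],
                              "label": [0, 0, 0, 1, 1, 0]})
        with pytest.raises(ArgumentError, match="water"):
            L.extract_signatures(bands_from_cube(cube), train,
                                 class_names=["urban", "water"])


class TestMlcDecisions:
    def two_class_1band(self, sigma2=1.0):
        return [L.ClassSignature(label=0, mean=[10.0], covariance=[[sigma2]],
                                 n_train=10),
                L.ClassSignature(label=1, mean=[100.0], covariance=[[sigma2]],
                                 n_train=10)]

    def test_nearest_mean_with_spherical_covariance(self):
        bands = bands_from_cube(np.array([[[12.0]]]))
        out = L.classify_mlc(bands, self.two_class_1band())
        assert out.labels[0, 0] == 0

    def test_midway_tie_goes_to_lowest_index(self):
        bands = bands_from_cube(np.array([[[55.0]]]))
        out = L.classify_mlc(bands, self.two_class_1band())
        assert out.labels[0, 0] == 0

    def test_priors_shift_the_boundary(self):
        bands = bands_from_cube(np.array([[[54.0]]]))
        sigs = self.two_class_1band(sigma2=400.0)
        equal = L.classify_mlc(bands, sigs)
        skewed = L.classify_mlc(bands, sigs, priors={0: 0.05, 1: 0.95})
        assert equal.labels[0, 0] == 0
        assert skewed.labels[0, 0] == 1

    def test_nodata_propagates(self):
        bands = bands_from_cube(np.array([[[12.0], [13.0]]]))
        bands[0].nodata_mask[0, 1] = True
        out = L.classify_mlc(bands, self.two_class_1band())
        assert out.labels[0, 1] == -1


class TestMlcAgainstBruteForce:
    def test_equals_density_maximization_on_synthetic_scene(self, scene):
        train = L.sample_truth_points(scene.truth_map, 40, seed=21)
        sigs = L.extract_signatures(scene.optical_bands, train)
        out = L.classify_mlc(scene.optical_bands, sigs)
        sub = np.s_[:50, :50]
        cube = np.stack([b.values for b in scene.optical_bands], axis=-1)
        dens = np.stack([
            multivariate_normal(mean=s.mean, cov=s.covariance)
            .logpdf(cube[sub].reshape(-1, 3))
            for s in sorted(sigs, key=lambda s: s.label)], axis=-1)
        assert np.array_equal(out.labels[sub].ravel(), dens.argmax(axis=-1))

    def test_equal_covariance_reduces_to_mahalanobis(self):
        rng = np.random.default_rng(7)
        cov = np.array([[4.0, 1.0], [1.0, 3.0]])
        means = rng.normal(scale=10, size=(4, 2))
        sigs = [L.ClassSignature(label=i, mean=m, covariance=cov, n_train=9)
                for i, m in enumerate(means)]
        cube = rng.normal(scale=10, size=(20, 20, 2))
        out = L.classify_mlc(bands_from_cube(cube), sigs)
        inv = np.linalg.inv(cov)
        x = cube.reshape(-1, 2)
        d2 = np.stack([np.einsum("ij,jk,ik->i", x - m, inv, x - m)
                       for m in means], axis=-1)
        assert np.array_equal(out.labels.ravel(), d2.argmin(axis=-1))

    def test_affine_scaling_leaves_labels_unchanged(self):
        rng = np.random.default_rng(11)
        means = rng.normal(scale=5, size=(3, 2))
        covs = [np.diag(rng.uniform(1, 3, 2)) for _ in range(3)]
        cube = rng.normal(scale=5, size=(15, 15, 2))
        c = 7.0
        sigs = [L.ClassSignature(label=i, mean=m, covariance=S, n_train=9)
                for i, (m, S) in enumerate(zip(means, covs))]
        scaled = [L.ClassSignature(label=i, mean=c * m,
                                   covariance=c**2 * S, n_train=9)
                  for i, (m, S) in enumerate(zip(means, covs))]
        a = L.classify_mlc(bands_from_cube(cube), sigs)
        b = L.classify_mlc(bands_from_cube(c * cube), scaled)
        assert np.array_equal(a.labels, b.labels)


class TestRecovery:
    def test_noise_free_scene_recovered_exactly(self):
        specs = L.default_class_specs(band_sd=0.0, thermal_sd=0.0)
        tm = L.generate_truth_map((60, 60), specs, seed=2)
        sc = L.generate_scene(tm, specs, seed=3)
        train = L.sample_truth_points(tm, 10, seed=4)
        sigs = L.extract_signatures(sc.optical_bands, train)
        out = L.classify_mlc(sc.optical_bands, sigs)
        assert np.array_equal(out.labels, tm.labels)

    def test_well_separated_scene_high_holdout_accuracy(self, scene):
        tm = scene.truth_map
        train = L.sample_truth_points(tm, 40, seed=31)
        test = L.sample_truth_points(tm, 40, seed=32)
        sigs = L.extract_signatures(scene.optical_bands, train)
        out = L.classify_mlc(scene.optical_bands, sigs,
                             class_names=tm.class_names)
        em = L.build_error_matrix(out, test)
        assert L.overall_accuracy(em) >= 99.0
        assert L.kappa(em) >= 0.98
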