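import numpy as np
import pandas as pd
import pytest

import lulcst as L
from lulcst.errors import ArgumentError


def grids_and_labels():
    lst = L.BandGrid(values=np.array([[30.0, 30.0], [20.0, 40.0]]))
    nd = L.BandGrid(values=np.array([[0.1, 0.2], [0.3, 0.4]]))
    labels = L.LabelMap(labels=np.array([[0, 0], [1, 1]]),
                        class_names=["c1", "c2"])
    return lst, nd, labels


class TestClassMeans:
    def test_constant_field_gives_the_constant(self):
        lst = L.BandGrid(values=np.full((4, 4), 25.0))
        nd = L.BandGrid(values=np.full((4, 4), 0.3))
        labels = L.LabelMap(labels=np.tile([0, 1], (4, 2)),
                            class_names=["a", "b"])
        df = L.class_means(lst, nd, labels).set_index("class")
        assert (df["mean_lst_c"] == 25.0).all()
        assert np.allclose(df["mean_ndvi"], 0.3)

    def test_hand_means_per_class(self):
        lst, nd, labels = grids_and_labels()
        df = L.class_means(lst, nd, labels).set_index("class")
        assert df.loc["c1", "mean_lst_c"] == pytest.approx(30.0)
        assert df.loc["c2", "mean_lst_c"] == pytest.approx(30.0)
        assert df.loc["c1", "mean_ndvi"] == pytest.approx(0.15)

    def test_nodata_pixels_excluded(self):
        lst, nd, labels = grids_and_labels()
        lst.nodata_mask[1, 1] = True
        df = L.class_means(lst, nd, labels).set_index("class")
        assert df.loc["c2", "mean_lst_c"] == pytest.approx(20.0)
        assert df.loc["c2", "n_pixels"] == 1


class TestPointSampling:
    def test_twenty_points_per_class_verified_against_map(self, truth_map):
        pts = L.sample_class_points(truth_map, 20, seed=5)
        assert len(pts) == 120
        assert (truth_map.labels[pts["row"], pts["col"]]
                == pts["label"]).all()

    def test_deterministic_per_seed(self, truth_map):
        assert L.sample_class_points(truth_map, 5, seed=9).equals(
            L.sample_class_points(truth_map, 5, seed=9))

    def test_single_point_per_class(self, truth_map):
        assert len(L.sample_class_points(truth_map, 1, seed=0)) == 6

    def test_undersized_class_named(self, truth_map):
        with pytest.raises(ArgumentError, match="pixels"):
            L.sample_class_points(truth_map, 10_000, seed=0)


class TestOls:
    def test_exact_collinearity(self):
        fit = L.fit_lst_ndvi([30.0, 29.0, 28.0], [0.1, 0.2, 0.3])
        assert fit.slope == pytest.approx(-10.0)
        assert fit.intercept == pytest.approx(31.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_closed_form_three_point_fit(self):
        fit = L.fit_lst_ndvi([30.0, 20.0, 25.0], [0.0, 1.0, 2.0])
        assert fit.slope == pytest.approx(-2.5)
        assert fit.intercept == pytest.approx(27.5)
        assert fit.r_squared == pytest.approx(0.25)

    def test_duplicating_every_point_changes_nothing(self):
        y = [30.0, 20.0, 25.0, 27.0]
        x = [0.0, 1.0, 2.0, 0.5]
        a = L.fit_lst_ndvi(y, x)
        b = L.fit_lst_ndvi(y * 2, x * 2)
        assert (a.slope, a.intercept, a.r_squared) == pytest.approx(
            (b.slope, b.intercept, b.r_squared))

    def test_passes_through_centroid(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-0.5, 0.8, 40)
        y = 30 - 8 * x + rng.normal(0, 1.5, 40)
        fit = L.fit_lst_ndvi(y, x)
        assert fit.predict(x.mean()) == pytest.approx(y.mean())

    def test_r_squared_equals_one_minus_sse_over_sst(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 30)
        y = 25 - 5 * x + rng.normal(0, 1, 30)
        fit = L.fit_lst_ndvi(y, x)
        pred = fit.slope * x + fit.intercept
        sse = ((y - pred) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert fit.r_squared == pytest.approx(1 - sse / sst, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ArgumentError):
            L.fit_lst_ndvi([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])


class TestParameterRecovery:
    def test_slope_recovered_within_three_standard_errors(self):
        """At the pipeline's sampling size (20 points/class), the true
        slope falls inside +-3 SE in >= 95% of replicates."""
        a, b, sigma, n = -12.0, 32.0, 1.0, 20
        hits = 0
        reps = 500
        root = np.random.SeedSequence(42).spawn(reps)
        for ss in root:
            rng = np.random.default_rng(ss)
            x = rng.uniform(0.0, 0.8, n)
            y = a * x + b + rng.normal(0, sigma, n)
            fit = L.fit_lst_ndvi(y, x)
            if abs(fit.slope - a) <= 3 * fit.stderr_slope:
                hits += 1
        assert hits / reps >= 0.95


def test_fit_per_class_produces_one_fit_per_class(scene, truth_map):
    nd = L.ndvi(scene.red, scene.nir)
    rad = L.toa_radiance(scene.thermal_band, scene.meta)
    bt = L.brightness_temperature(rad, scene.meta)
    lst = L.land_surface_temperature(
        bt, L.emissivity(L.proportion_vegetation(nd)), scene.meta)
    df = L.fit_per_class(lst, nd, truth_map, n_per_class=20, seed=1)
    assert len(df) == 6
    assert ((0 <= df["r_squared"]) & (df["r_squared"] <= 1)).all()
    assert (df["n_points"] == 20).all()
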