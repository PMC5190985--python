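"""NDVI classification, calibration fitting and raster reclassification."""

import numpy as np
import pytest

from vinelai.mapping import (
    NdviRaster,
    classify_ndvi,
    fit_calibration,
    read_raster,
    reclassify_per_class,
    reclassify_to_lai,
    write_raster,
)
from vinelai.synth import make_ndvi_field


def uniform_raster(lo=0.0, hi=1.0, n=100):
    return NdviRaster(grid=np.linspace(lo, hi, n).reshape(10, 10))


class TestClassify:
    def test_equal_interval_bounds(self):
        cls = classify_ndvi(uniform_raster(), k=5)
        assert cls.class_bounds == pytest.approx([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        assert set(np.unique(cls.labels)) == {1, 2, 3, 4, 5}

    def test_constant_raster_rejected(self):
        with pytest.raises(ValueError):
            classify_ndvi(NdviRaster(grid=np.full((5, 5), 0.5)), k=5)

    def test_single_class(self):
        cls = classify_ndvi(uniform_raster(), k=1)
        assert np.all(cls.labels == 1)

    def test_maximum_belongs_to_top_class(self):
        cls = classify_ndvi(uniform_raster(), k=5)
        assert cls.labels.ravel()[-1] == 5

    def test_quantile_mode_balances_counts(self):
        rng = np.random.default_rng(2)
        raster = NdviRaster(grid=rng.uniform(0, 1, (20, 20)))
        cls = classify_ndvi(raster, k=4, method="quantile")
        counts = [np.sum(cls.labels == c) for c in range(1, 5)]
        assert max(counts) - min(counts) <= 2

    def test_jenks_mode_separates_planted_clusters(self):
        vals = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)])
        vals += np.random.default_rng(3).normal(0, 0.01, 100)
        cls = classify_ndvi(NdviRaster(grid=vals.reshape(10, 10)), k=2, method="jenks")
        labels = cls.labels.ravel()
        assert set(labels[:50]) == {1} and set(labels[50:]) == {2}

    def test_nodata_gets_label_zero(self):
        grid = np.linspace(0, 1, 100).reshape(10, 10)
        grid[0, 0] = np.nan
        cls = classify_ndvi(NdviRaster(grid=grid), k=3)
        assert cls.labels[0, 0] == 0


class TestCalibration:
    def test_exact_line(self):
        ndvi = np.array([0.1, 0.3, 0.5, 0.7])
        fit = fit_calibration(ndvi, 2 * ndvi)
        assert fit.slope == pytest.approx(2.0) and fit.intercept == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_two_point_interpolation(self):
        fit = fit_calibration([0.2, 0.8], [0.5, 2.0])
        assert fit.r2 == 1.0
        assert fit.predict(0.2) == pytest.approx(0.5)

    def test_constant_ndvi_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([0.4, 0.4, 0.4], [1.0, 2.0, 3.0])

    def test_noisy_recovery_within_three_se(self):
        # theoretical OLS standard errors from the known noise level
        a, b, sigma = 3.5, -0.4, 0.05
        rng = np.random.default_rng(17)
        ndvi = np.linspace(0.2, 0.9, 5)
        laiv = a * ndvi + b + rng.normal(0, sigma, 5)
        fit = fit_calibration(ndvi, laiv)
        ssx = np.sum((ndvi - ndvi.mean()) ** 2)
        se_a = sigma / np.sqrt(ssx)
        se_b = sigma * np.sqrt(1 / ndvi.size + ndvi.mean() ** 2 / ssx)
        assert abs(fit.slope - a) < 3 * se_a
        assert abs(fit.intercept - b) < 3 * se_b


class TestReclassify:
    def test_linear_map(self):
        raster = NdviRaster(grid=np.array([[0.4]]))
        from vinelai.mapping import CalibrationFit

        lai = reclassify_to_lai(raster, CalibrationFit(slope=2, intercept=0, r2=1, n=2))
        assert lai.grid[0, 0] == pytest.approx(0.8)

    def test_nodata_preserved_and_floor_warns(self):
        from vinelai.mapping import CalibrationFit

        raster = NdviRaster(grid=np.array([[0.1, np.nan], [0.9, 0.5]]))
        fit = CalibrationFit(slope=2.0, intercept=-0.5, r2=1, n=2)
        with pytest.warns(UserWarning, match="floored"):
            lai = reclassify_to_lai(raster, fit)
        assert np.isnan(lai.grid[0, 1])
        assert lai.grid[0, 0] == 0.0  # 2·0.1−0.5 < 0 floored

    def test_monotone_in_ndvi(self):
        from vinelai.mapping import CalibrationFit

        raster = uniform_raster()
        lai = reclassify_to_lai(raster, CalibrationFit(slope=1.7, intercept=0.1, r2=1, n=3))
        flat_in = raster.grid.ravel()
        flat_out = lai.grid.ravel()
        assert np.all(np.diff(flat_out[np.argsort(flat_in)]) >= 0)

    def test_round_trip_through_synthetic_field(self):
        a, b = 2.5, 0.3
        lai_true = np.abs(np.random.default_rng(4).uniform(0.4, 2.5, (12, 12)))
        ndvi = make_ndvi_field(lai_true, a, b, noise_sd=0.0)
        fit = fit_calibration(ndvi.grid.ravel()[:50], a * ndvi.grid.ravel()[:50] + b)
        lai = reclassify_to_lai(ndvi, fit)
        assert lai.grid == pytest.approx(lai_true, abs=1e-10)

    def test_class_means_map_linearly(self):
        from vinelai.mapping import CalibrationFit

        raster = uniform_raster()
        cls = classify_ndvi(raster, k=4)
        fit = CalibrationFit(slope=1.2, intercept=0.2, r2=1, n=5)
        lai = reclassify_to_lai(raster, fit)
        for c in range(1, 5):
            sel = cls.labels == c
            assert lai.grid[sel].mean() == pytest.approx(
                fit.slope * raster.grid[sel].mean() + fit.intercept, abs=1e-12
            )

    def test_per_class_mode_constant_within_class(self):
        from vinelai.mapping import CalibrationFit

        raster = uniform_raster()
        cls = classify_ndvi(raster, k=3)
        fit = CalibrationFit(slope=2.0, intercept=0.0, r2=1, n=4)
        lai = reclassify_per_class(raster, cls, fit)
        for c in range(1, 4):
            vals = lai.grid[cls.labels == c]
            assert np.unique(vals).size == 1
            assert vals[0] == pytest.approx(2.0 * cls.class_means[c - 1])


class TestRasterIO:
    def test_ascii_grid_round_trip(self, tmp_path):
        grid = np.array([[0.1, 0.2], [np.nan, 0.4]])
        raster = NdviRaster(grid=grid, cellsize=2.5, xllcorner=100.0, yllcorner=200.0)
        path = tmp_path / "ndvi.asc"
        write_raster(raster, path)
        back = read_raster(path)
        assert back.cellsize == 2.5 and back.xllcorner == 100.0
        assert np.allclose(back.grid, grid, equal_nan=True)

    def test_tiff_round_trip(self, tmp_path):
        grid = np.random.default_rng(0).uniform(-0.2, 0.9, (6, 6)).astype(np.float32)
        path = tmp_path / "ndvi.tif"
        write_raster(NdviRaster(grid=grid), path)
        back = read_raster(path)
        assert np.allclose(back.grid, grid, atol=1e-7)
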