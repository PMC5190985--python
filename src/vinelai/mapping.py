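"""Smart scouting: NDVI vigor classes, calibration, and LAI maps.

A high-resolution NDVI raster captures *relative* vigor; a handful of
in-situ LAI estimates anchors it to an *absolute* scale.  The chain is:

1. classify the NDVI raster into K vigor classes (default 5) to choose
   where to sample;
2. fit an ordinary least-squares line  LAIv = a·NDVI + b  through the
   (NDVI, LAIv) pairs measured at the sampled areas;
3. reclassify the raster cell-wise through the fitted line into an LAI
   map (negative predictions floored at 0, no-data preserved).

Raster I/O: ESRI ASCII grid (plain text, always available) and plain TIFF.
No-data cells are NaN in memory and the ``nodata`` sentinel on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NdviRaster",
    "ClassifiedRaster",
    "CalibrationFit",
    "read_raster",
    "write_raster",
    "classify_ndvi",
    "fit_calibration",
    "reclassify_to_lai",
    "reclassify_per_class",
]


# ---------------------------------------------------------------------------
# Raster container and I/O


@dataclass
class NdviRaster:
    """A 2-D grid of NDVI (or LAI) values; NaN marks no-data cells."""

    grid: np.ndarray
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise ValueError("raster grid must be two-dimensional")
        g = np.where(g == self.nodata, np.nan, g)
        self.grid = g

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.grid)

    def valid_values(self) -> np.ndarray:
        return self.grid[self.valid]

    def like(self, grid: np.ndarray) -> "NdviRaster":
        """A new raster sharing this one's geometry."""
        return NdviRaster(
            grid=grid, cellsize=self.cellsize, xllcorner=self.xllcorner,
            yllcorner=self.yllcorner, nodata=self.nodata,
        )


def read_raster(path: str | Path) -> NdviRaster:
    """Read an ESRI ASCII grid (.asc/.txt) or a plain TIFF (.tif/.tiff)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return NdviRaster(grid=tifffile.imread(path).astype(float))
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = np.loadtxt(lines[n_header:], ndmin=2)
    if "nrows" in header and grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid shape disagrees with the ASCII header")
    return NdviRaster(
        grid=grid,
        cellsize=header.get("cellsize", 1.0),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_raster(raster: NdviRaster, path: str | Path) -> None:
    """Write as ESRI ASCII grid, or plain TIFF for a .tif/.tiff suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, raster.grid.astype(np.float32))
        return
    g = np.where(np.isnan(raster.grid), raster.nodata, raster.grid)
    nrows, ncols = g.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {raster.xllcorner:g}\nyllcorner {raster.yllcorner:g}\n"
            f"cellsize {raster.cellsize:g}\nNODATA_value {raster.nodata:g}\n"
        )
        np.savetxt(fh, g, fmt="%.10g")


# ---------------------------------------------------------------------------
# Vigor classification


@dataclass
class ClassifiedRaster:
    """Class labels 1..K per valid cell (0 = no-data) with break points."""

    labels: np.ndarray
    class_bounds: np.ndarray   # K+1 strictly increasing breakpoints
    class_means: np.ndarray    # mean NDVI per class

    @property
    def k(self) -> int:
        return len(self.class_bounds) - 1


def _natural_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """Jenks-style breaks via 1-D k-means (deterministic seed)."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(values.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    mids = (centers[:-1] + centers[1:]) / 2.0
    return np.concatenate([[values.min()], mids, [values.max()]])


def classify_ndvi(raster: NdviRaster, k: int = 5, method: str = "equal") -> ClassifiedRaster:
    """Partition valid cells into ``k`` vigor classes.

    ``method``: "equal" (equal-interval between min and max, the default and
    the deterministic reclassify convention of desktop GIS), "quantile", or
    "jenks" (natural breaks by 1-D k-means).
    """
    values = raster.valid_values()
    if np.unique(values).size < k:
        raise ValueError(
            f"need at least {k} distinct NDVI values for {k} classes, "
            f"got {np.unique(values).size}"
        )
    lo, hi = float(values.min()), float(values.max())
    if method == "equal":
        bounds = np.linspace(lo, hi, k + 1)
    elif method == "quantile":
        bounds = np.quantile(values, np.linspace(0, 1, k + 1))
    elif method == "jenks":
        bounds = _natural_breaks(values, k)
    else:
        raise ValueError(f"unknown classification method {method!r}")
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("degenerate class breaks (ties in the value distribution)")

    labels = np.zeros(raster.grid.shape, dtype=int)
    v = raster.grid[raster.valid]
    # right-closed last bin so the maximum belongs to class K
    lab = np.clip(np.searchsorted(bounds[1:-1], v, side="right") + 1, 1, k)
    labels[raster.valid] = lab
    means = np.array([v[lab == c].mean() if np.any(lab == c) else np.nan
                      for c in range(1, k + 1)])
    return ClassifiedRaster(labels=labels, class_bounds=bounds, class_means=means)


# ---------------------------------------------------------------------------
# Calibration and reclassification


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line laiv = slope·ndvi + intercept with its R²."""

    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, ndvi: np.ndarray | float) -> np.ndarray | float:
        return self.slope * ndvi + self.intercept


def fit_calibration(
    ndvi: np.ndarray | pd.Series, laiv: np.ndarray | pd.Series
) -> CalibrationFit:
    """Fit the NDVI→LAI line through the in-situ sampling points."""
    x = np.asarray(ndvi, dtype=float)
    y = np.asarray(laiv, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (ndvi, laiv) pairs of equal length")
    if np.ptp(x) == 0:
        raise ValueError("constant NDVI: calibration line undefined")
    lin = stats.linregress(x, y)
    r2 = 1.0 if x.size == 2 else float(lin.rvalue**2)
    return CalibrationFit(
        slope=float(lin.slope), intercept=float(lin.intercept), r2=r2, n=x.size
    )


def reclassify_to_lai(raster: NdviRaster, fit: CalibrationFit) -> NdviRaster:
    """Map every valid NDVI cell through the calibration line.

    Predicted LAI below zero is floored at 0 (LAI is non-negative); the
    number of floored cells is reported in a warning.  No-data propagates.
    """
    lai = fit.predict(raster.grid)
    n_floored = int(np.nansum(lai < 0))
    if n_floored:
        warnings.warn(f"{n_floored} cells predicted negative LAI; floored at 0",
                      stacklevel=2)
        lai = np.where(lai < 0, 0.0, lai)
    return raster.like(lai)


def reclassify_per_class(
    raster: NdviRaster, classified: ClassifiedRaster, fit: CalibrationFit
) -> NdviRaster:
    """Per-class constant map: each class gets the line's value at its mean NDVI."""
    class_lai = np.maximum(fit.predict(classified.class_means), 0.0)
    lai = np.full(raster.grid.shape, np.nan)
    for c in range(1, classified.k + 1):
        lai[classified.labels == c] = class_lai[c - 1]
    return raster.like(lai)
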