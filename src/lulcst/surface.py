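"""NDVI, proportion of vegetation, emissivity and land surface temperature.

The vegetation index is the usual normalized difference,
NDVI = (NIR − RED)/(NIR + RED), computed here directly on digital numbers
(reflectance grids work identically).  Fractional vegetation cover is the
squared min–max scaling PV = ((NDVI − NDVImin)/(NDVImax − NDVImin))², with
the ratio clipped to [0, 1] before squaring; emissivity is the linear
NDVI-threshold form E = 0.004·PV + 0.986, so E ∈ [0.986, 0.990].

LST uses the single-channel emissivity correction

    LST = BT / (1 + (λ·BT/c2)·ln E),      c2 = 14388 µm·K,

with λ the thermal-band wavelength in µm.  Two evaluation modes exist
because the correction is dimensionally meaningful only with BT in kelvin:

* ``celsius_literal`` (default) plugs BT in °C straight into the formula —
  the convention some published analyses follow;
* ``kelvin_physical`` evaluates it with BT in kelvin and converts the
  result back to °C.

The mode used is recorded on the returned grid's ``band_id``.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ArgumentError
from .raster_io import BandGrid, SceneMeta

log = logging.getLogger(__name__)

C2_UM_K = 14388.0
EMISSIVITY_OFFSET = 0.986
EMISSIVITY_SLOPE = 0.004


def ndvi(red: BandGrid, nir: BandGrid) -> BandGrid:
    """Normalized difference vegetation index, (NIR − RED)/(NIR + RED).

    Pixels where NIR + RED = 0 are flagged nodata.
    """
    if red.shape != nir.shape:
        raise ArgumentError(
            f"red shape {red.shape} != nir shape {nir.shape}")
    r = red.values.astype(float)
    n = nir.values.astype(float)
    denom = n + r
    zero = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (n - r) / denom
    out = np.where(zero, np.nan, out)
    mask = red.nodata_mask | nir.nodata_mask | zero
    return BandGrid(values=out, nodata_mask=mask,
                    pixel_size_m=red.pixel_size_m, band_id="ndvi")


def ndvi_range(grid: BandGrid) -> tuple[float, float]:
    """Observed (min, max) NDVI over non-nodata pixels."""
    vals = grid.values[~grid.nodata_mask]
    if vals.size == 0:
        raise ArgumentError("all pixels are nodata; NDVI range undefined")
    return float(vals.min()), float(vals.max())


def proportion_vegetation(ndvi_grid: BandGrid, ndvi_min: float | None = None,
                          ndvi_max: float | None = None) -> BandGrid:
    """Fractional vegetation cover from NDVI via squared min–max scaling.

    When the scene extremes are not supplied they are read from the grid
    itself (nodata excluded), mirroring how the thresholds are taken "from
    the NDVI image" in practice.
    """
    if ndvi_min is None or ndvi_max is None:
        lo, hi = ndvi_range(ndvi_grid)
        ndvi_min = lo if ndvi_min is None else ndvi_min
        ndvi_max = hi if ndvi_max is None else ndvi_max
    if not ndvi_max > ndvi_min:
        raise ArgumentError("ndvi_max must exceed ndvi_min")
    ratio = (ndvi_grid.values.astype(float) - ndvi_min) / (ndvi_max - ndvi_min)
    pv = np.clip(ratio, 0.0, 1.0) ** 2
    return ndvi_grid.with_values(pv, band_id="proportion_vegetation")


def emissivity(pv: BandGrid) -> BandGrid:
    """Land surface emissivity E = 0.004·PV + 0.986."""
    vals = pv.values.astype(float)
    ok = pv.nodata_mask | ((vals >= 0.0) & (vals <= 1.0))
    if not ok.all():
        raise ArgumentError("proportion of vegetation must lie in [0, 1]")
    return pv.with_values(EMISSIVITY_SLOPE * vals + EMISSIVITY_OFFSET,
                          band_id="emissivity")


def land_surface_temperature(bt: BandGrid, emis: BandGrid, meta: SceneMeta,
                             bt_scale: str = "celsius_literal",
                             c2: float = C2_UM_K) -> BandGrid:
    """Emissivity-corrected LST (°C) from brightness temperature.

    Parameters
    ----------
    bt
        Brightness temperature in °C.
    emis
        Emissivity grid with values in (0, 1].
    meta
        Supplies the wavelength λ (µm) for the sensor's thermal band.
    bt_scale
        ``"celsius_literal"`` or ``"kelvin_physical"`` (see module docs).
    """
    if bt_scale not in ("celsius_literal", "kelvin_physical"):
        raise ArgumentError(f"unknown bt_scale {bt_scale!r}")
    if bt.shape != emis.shape:
        raise ArgumentError("BT and emissivity grids must share a shape")
    e = emis.values.astype(float)
    valid = ~(bt.nodata_mask | emis.nodata_mask)
    if np.any(valid & (e <= 0)):
        raise ArgumentError("emissivity must be positive")
    if np.any(valid & (e > 1)):
        raise ArgumentError("emissivity must not exceed 1")

    t = bt.values.astype(float)
    offset = 0.0
    if bt_scale == "kelvin_physical":
        t = t + 273.15
        offset = -273.15
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 + (meta.wavelength_um * t / c2) * np.log(e)
        lst = t / denom + offset
    bad = valid & (denom <= 0)
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("%d pixels had a nonpositive LST denominator; "
                    "flagged nodata", n_bad)
    lst = np.where(bad, np.nan, lst)
    out = bt.with_values(lst, band_id=f"lst_c[{bt_scale}]", extra_mask=bad)
    out.nodata_mask |= emis.nodata_mask
    return out
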