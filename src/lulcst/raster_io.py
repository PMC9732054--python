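"""Raster band containers, TIFF input/output and study-area clipping.

Rasters are plain (single- or multi-band) TIFF files.  Grid metadata that a
geospatial container would normally carry — pixel size in metres, the nodata
sentinel and a band label — is stored as a JSON object in the TIFF
``ImageDescription`` tag, so files round-trip without any sidecar.  There is
no coordinate-reference-system handling: all geometry is expressed in pixel
coordinates (columns along x, rows along y), which is sufficient for the
area and change statistics this package computes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ArgumentError, ConfigError

log = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0


@dataclass
class BandGrid:
    """One raster band: values plus a nodata mask and the pixel size.

    Parameters
    ----------
    values
        2-D array of per-pixel numbers (digital numbers or physical units).
    nodata_mask
        2-D boolean array of the same shape; ``True`` marks nodata cells.
    pixel_size_m
        Length of a (square) pixel edge in metres; must be positive.
    band_id
        Free-text band label (e.g. ``"thermal"`` or ``"B4"``).
    """

    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    pixel_size_m: float = 30.0
    band_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ArgumentError("band values must be a 2-D array")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ArgumentError(
                f"nodata_mask shape {self.nodata_mask.shape} != "
                f"values shape {self.values.shape}"
            )
        if not self.pixel_size_m > 0:
            raise ArgumentError("pixel_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked(self, fill: float = np.nan) -> np.ndarray:
        """Return float values with nodata cells replaced by *fill*."""
        out = self.values.astype(float, copy=True)
        out[self.nodata_mask] = fill
        return out

    def with_values(self, values: np.ndarray, band_id: str | None = None,
                    extra_mask: np.ndarray | None = None) -> "BandGrid":
        """New grid with the same geometry, propagating this grid's mask."""
        mask = self.nodata_mask.copy()
        if extra_mask is not None:
            mask |= extra_mask
        return BandGrid(values=np.asarray(values), nodata_mask=mask,
                        pixel_size_m=self.pixel_size_m,
                        band_id=self.band_id if band_id is None else band_id)


@dataclass
class SceneMeta:
    """Radiometric and thermal calibration constants for one scene.

    ``TM``-style scenes (Landsat 4/5) are rescaled through the
    LMax/LMin–QcalMax/QcalMin endpoints; ``OLI_TIRS`` scenes (Landsat 8)
    through the multiplicative/additive factors ML and AL plus the band
    correction Oi.  K1 (W·m⁻²·sr⁻¹·µm⁻¹) and K2 (K) invert the Planck
    relation for the thermal band; ``wavelength_um`` is the emitted-radiance
    wavelength λ used by the single-channel LST formula.
    """

    sensor: str  # "TM" | "OLI_TIRS"
    K1: float
    K2: float
    wavelength_um: float
    ML: float = 0.0
    AL: float = 0.0
    Oi: float = 0.0
    LMax_lambda: float = 0.0
    LMin_lambda: float = 0.0
    QcalMax: float = 255.0
    QcalMin: float = 1.0

    def __post_init__(self) -> None:
        if self.sensor not in ("TM", "OLI_TIRS"):
            raise ConfigError(f"unknown sensor {self.sensor!r}")
        if not (self.K1 > 0 and self.K2 > 0 and self.wavelength_um > 0):
            raise ConfigError("K1, K2 and wavelength_um must be positive")
        if not self.QcalMax > self.QcalMin:
            raise ConfigError("QcalMax must exceed QcalMin")
        if self.sensor == "TM" and not self.LMax_lambda > self.LMin_lambda:
            raise ConfigError("TM scenes require LMax_lambda > LMin_lambda")
        if self.sensor == "OLI_TIRS" and self.ML == 0:
            raise ConfigError("OLI_TIRS scenes require a nonzero ML")


# Canonical constants for the two supported sensors: Landsat 5 TM band 6
# (K1 = 607.76, K2 = 1260.56, λ = 11.5 µm) and Landsat 8 TIRS band 10
# (λ = 10.8 µm).
def landsat5_tm_meta(LMax_lambda: float = 15.303, LMin_lambda: float = 1.238,
                     QcalMax: float = 255.0, QcalMin: float = 1.0) -> SceneMeta:
    """TM metadata with the Landsat 5 band-6 thermal constants."""
    return SceneMeta(sensor="TM", K1=607.76, K2=1260.56, wavelength_um=11.5,
                     LMax_lambda=LMax_lambda, LMin_lambda=LMin_lambda,
                     QcalMax=QcalMax, QcalMin=QcalMin)


def landsat8_oli_meta(ML: float = 3.342e-4, AL: float = 0.1, Oi: float = 0.29,
                      K1: float = 774.8853, K2: float = 1321.0789,
                      QcalMax: float = 65535.0, QcalMin: float = 1.0) -> SceneMeta:
    """OLI/TIRS metadata with Landsat 8 band-10 defaults."""
    return SceneMeta(sensor="OLI_TIRS", K1=K1, K2=K2, wavelength_um=10.8,
                     ML=ML, AL=AL, Oi=Oi, QcalMax=QcalMax, QcalMin=QcalMin)


def write_band(grid: BandGrid, path: str | Path,
               nodata: float = DEFAULT_NODATA) -> Path:
    """Write a band to TIFF, filling nodata cells with *nodata*.

    Grid metadata (pixel size, nodata value, band id) goes into the
    ImageDescription tag as JSON.
    """
    path = Path(path)
    arr = np.array(grid.values, copy=True)
    if grid.nodata_mask.any():
        if np.issubdtype(arr.dtype, np.integer):
            info = np.iinfo(arr.dtype)
            if not info.min <= nodata <= info.max:
                raise ArgumentError(
                    f"nodata value {nodata} not representable in {arr.dtype}")
        arr[grid.nodata_mask] = nodata
    desc = json.dumps({"pixel_size_m": grid.pixel_size_m, "nodata": nodata,
                       "band_id": grid.band_id})
    tifffile.imwrite(path, arr, description=desc)
    return path


def write_bands(grids: list[BandGrid], path: str | Path,
                nodata: float = DEFAULT_NODATA) -> Path:
    """Write several same-shape bands as one multi-band TIFF."""
    if not grids:
        raise ArgumentError("no bands to write")
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ArgumentError("bands must share one shape")
    arrs = []
    for g in grids:
        a = np.array(g.values, copy=True)
        a[g.nodata_mask] = nodata
        arrs.append(a)
    desc = json.dumps({"pixel_size_m": grids[0].pixel_size_m, "nodata": nodata,
                       "band_id": [g.band_id for g in grids]})
    tifffile.imwrite(Path(path), np.stack(arrs), description=desc,
                     photometric="minisblack")
    return Path(path)


def _parse_description(raw: str | None) -> dict:
    if not raw:
        return {}
    try:
        meta = json.loads(raw)
    except (TypeError, json.JSONDecodeError):
        return {}
    return meta if isinstance(meta, dict) else {}


def read_band(path: str | Path, band_index: int = 1) -> BandGrid:
    """Read one band (1-based *band_index*) from a TIFF file."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such raster file: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = _parse_description(tif.pages[0].description)
    if data.ndim == 2:
        data = data[None, ...]
    nbands = data.shape[0]
    if not 1 <= band_index <= nbands:
        raise ArgumentError(
            f"band_index {band_index} out of range for {nbands}-band file")
    values = data[band_index - 1]
    nodata = meta.get("nodata")
    mask = (np.zeros(values.shape, dtype=bool) if nodata is None
            else values == nodata)
    band_id = meta.get("band_id", "")
    if isinstance(band_id, list):
        band_id = band_id[band_index - 1] if band_index <= len(band_id) else ""
    return BandGrid(values=values, nodata_mask=mask,
                    pixel_size_m=float(meta.get("pixel_size_m", 30.0)),
                    band_id=str(band_id))


_META_SYNONYMS = {
    "LMAX": "LMax_lambda", "LMIN": "LMin_lambda",
    "LMAX_LAMBDA": "LMax_lambda", "LMIN_LAMBDA": "LMin_lambda",
    "QCALMAX": "QcalMax", "QCALMIN": "QcalMin",
    "K1": "K1", "K2": "K2", "ML": "ML", "AL": "AL", "OI": "Oi",
    "WAVELENGTH_UM": "wavelength_um", "SENSOR": "sensor",
}

_REQUIRED = {
    "TM": ["K1", "K2", "WAVELENGTH_UM", "LMAX", "LMIN", "QCALMAX", "QCALMIN"],
    "OLI_TIRS": ["K1", "K2", "WAVELENGTH_UM", "ML", "AL", "OI"],
}


def read_scene_meta(path: str | Path) -> SceneMeta:
    """Parse an MTL-style flat ``KEY = value`` metadata file.

    One key per line, ``#`` starts a comment, keys are case-insensitive.
    Required keys depend on the declared SENSOR.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such metadata file: {path}")
    raw: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"malformed metadata line: {line!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        raw[key.upper()] = val
    if "SENSOR" not in raw:
        raise ConfigError("missing required metadata key: SENSOR")
    sensor = raw["SENSOR"].upper()
    if sensor not in _REQUIRED:
        raise ConfigError(f"unknown SENSOR value {raw['SENSOR']!r}")
    fields: dict[str, float | str] = {"sensor": sensor}
    for key in _REQUIRED[sensor]:
        if key not in raw:
            raise ConfigError(f"missing required metadata key: {key}")
    for key, val in raw.items():
        if key == "SENSOR":
            continue
        if key in _META_SYNONYMS:
            fields[_META_SYNONYMS[key]] = float(val)
    return SceneMeta(**fields)  # type: ignore[arg-type]


def write_scene_meta(meta: SceneMeta, path: str | Path) -> Path:
    """Write metadata in the flat key=value dialect read_scene_meta parses."""
    lines = [f"SENSOR = {meta.sensor}", f"K1 = {meta.K1!r}",
             f"K2 = {meta.K2!r}", f"WAVELENGTH_UM = {meta.wavelength_um!r}"]
    if meta.sensor == "TM":
        lines += [f"LMAX = {meta.LMax_lambda!r}", f"LMIN = {meta.LMin_lambda!r}"]
    else:
        lines += [f"ML = {meta.ML!r}", f"AL = {meta.AL!r}", f"OI = {meta.Oi!r}"]
    lines += [f"QCALMAX = {meta.QcalMax!r}", f"QCALMIN = {meta.QcalMin!r}"]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def clip_to_mask(grid: BandGrid, mask: np.ndarray) -> BandGrid:
    """Set cells outside *mask* (True = keep) to nodata; keep the rest."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ArgumentError(
            f"mask shape {mask.shape} != grid shape {grid.shape}")
    return grid.with_values(grid.values.copy(), extra_mask=~mask)


def mask_from_polygon(geometry, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon (GeoJSON mapping or shapely geometry) to a mask.

    Pixel coordinates: x = column, y = row.  A pixel is inside when its
    centre (col + 0.5, row + 0.5) falls inside the polygon.
    """
    import shapely
    from shapely.geometry import shape as shapely_shape

    geom = geometry if isinstance(geometry, shapely.Geometry) else \
        shapely_shape(geometry)
    rows, cols = shape
    cc, rr = np.meshgrid(np.arange(cols) + 0.5, np.arange(rows) + 0.5)
    return shapely.contains_xy(geom, cc.ravel(), rr.ravel()).reshape(shape)
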