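"""Thermal-band digital numbers → TOA radiance → brightness temperature.

The radiometric chain is the standard USGS linear rescaling: OLI/TIRS scenes
use the multiplicative/additive factors (Lλ = ML·Qcal + (AL − Oi)), TM
scenes the two-point endpoint form

    Lλ = (LMaxλ − LMinλ)/(QcalMax − QcalMin) · (Qcal − QcalMin) + LMinλ,

which maps QcalMin → LMinλ and QcalMax → LMaxλ exactly.  Brightness
temperature inverts the Planck relation with the sensor's thermal constants,

    BT = K2 / ln(K1/Lλ + 1) − 273.15,

yielding degrees Celsius.  Digital numbers outside [QcalMin, QcalMax] are
clamped (with a logged count) so saturated pixels still produce a value.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ArgumentError
from .raster_io import BandGrid, SceneMeta

log = logging.getLogger(__name__)

ABSOLUTE_ZERO_C = -273.15


def _clamp_dn(qcal: BandGrid, meta: SceneMeta) -> np.ndarray:
    vals = qcal.values.astype(float)
    out_of_range = ((vals < meta.QcalMin) | (vals > meta.QcalMax)) \
        & ~qcal.nodata_mask
    n = int(out_of_range.sum())
    if n:
        log.warning("clamped %d DN values outside [%g, %g]",
                    n, meta.QcalMin, meta.QcalMax)
    return np.clip(vals, meta.QcalMin, meta.QcalMax)


def toa_radiance_oli(qcal: BandGrid, meta: SceneMeta) -> BandGrid:
    """TOA spectral radiance for an OLI/TIRS scene: ML·Qcal + (AL − Oi)."""
    if meta.sensor != "OLI_TIRS":
        raise ArgumentError(f"expected OLI_TIRS metadata, got {meta.sensor}")
    lam = meta.ML * qcal.values.astype(float) + (meta.AL - meta.Oi)
    return qcal.with_values(lam, band_id="radiance")


def toa_radiance_tm(qcal: BandGrid, meta: SceneMeta, *,
                    literal_eq2: bool = False) -> BandGrid:
    """TOA spectral radiance for a TM scene via the LMax/LMin endpoints.

    ``literal_eq2=True`` evaluates gain × ((Qcal − QcalMin) + LMinλ), an
    alternative parenthesization sometimes seen in print; it breaks the
    endpoint identities and exists only for comparison.
    """
    if meta.sensor != "TM":
        raise ArgumentError(f"expected TM metadata, got {meta.sensor}")
    if meta.QcalMax == meta.QcalMin:
        raise ArgumentError("QcalMax equals QcalMin; gain undefined")
    gain = (meta.LMax_lambda - meta.LMin_lambda) / (meta.QcalMax - meta.QcalMin)
    dn = _clamp_dn(qcal, meta)
    if literal_eq2:
        lam = gain * ((dn - meta.QcalMin) + meta.LMin_lambda)
    else:
        lam = gain * (dn - meta.QcalMin) + meta.LMin_lambda
    return qcal.with_values(lam, band_id="radiance")


def toa_radiance(qcal: BandGrid, meta: SceneMeta) -> BandGrid:
    """Sensor-dispatching TOA radiance."""
    if meta.sensor == "TM":
        return toa_radiance_tm(qcal, meta)
    return toa_radiance_oli(qcal, meta)


def brightness_temperature(radiance: BandGrid, meta: SceneMeta) -> BandGrid:
    """Brightness temperature in °C: K2 / ln(K1/Lλ + 1) − 273.15.

    Pixels whose radiance makes the logarithm's argument nonpositive
    (Lλ ≤ −K1 or Lλ = 0 with the wrong sign) are flagged nodata and counted
    in a logged warning rather than raising.
    """
    lam = radiance.values.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = meta.K1 / lam + 1.0
        bad = ~radiance.nodata_mask & ((arg <= 0) | (lam <= 0))
        bt = meta.K2 / np.log(arg) + ABSOLUTE_ZERO_C
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("%d pixels had a nonpositive Planck-log argument; "
                    "flagged nodata", n_bad)
    bt = np.where(bad, np.nan, bt)
    return radiance.with_values(bt, band_id="brightness_temperature_c",
                                extra_mask=bad)


def brightness_temperature_kelvin(radiance: BandGrid,
                                  meta: SceneMeta) -> BandGrid:
    """Brightness temperature in kelvin (no −273.15 shift)."""
    bt_c = brightness_temperature(radiance, meta)
    return bt_c.with_values(bt_c.values - ABSOLUTE_ZERO_C,
                            band_id="brightness_temperature_k")
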