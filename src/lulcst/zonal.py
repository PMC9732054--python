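"""Per-class LST/NDVI summaries and the per-class LST-on-NDVI regression.

``class_means`` gives the zonal arithmetic means of LST and NDVI over each
mapped class.  The temperature–greenness relationship is quantified per
class by ordinary least squares of LST (response, °C) on NDVI (predictor,
dimensionless) at a seeded random sample of pixels — 20 per class by
default.  R² is the squared Pearson correlation of the sampled pairs; the
slope's sign carries the direction of the relationship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import NODATA_LABEL, LabelMap
from .errors import ArgumentError
from .raster_io import BandGrid

log = logging.getLogger(__name__)


@dataclass
class RegressionFit:
    """OLS fit of LST on NDVI for one class."""

    label: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    stderr_slope: float = float("nan")

    def predict(self, ndvi_value: float) -> float:
        return self.slope * ndvi_value + self.intercept


def class_means(lst: BandGrid, ndvi: BandGrid, labels: LabelMap
                ) -> pd.DataFrame:
    """Mean LST and NDVI per class over that class's non-nodata pixels.

    Classes with no usable pixels are omitted with a logged warning.
    """
    if lst.shape != ndvi.shape or lst.shape != labels.shape:
        raise ArgumentError("LST, NDVI and label grids must share a shape")
    rows = []
    present = np.unique(labels.labels)
    for label in present[present != NODATA_LABEL]:
        sel = (labels.labels == label) & ~lst.nodata_mask & ~ndvi.nodata_mask
        n = int(sel.sum())
        if n == 0:
            log.warning("class %s has no usable pixels; omitted",
                        labels.name_of(int(label)))
            continue
        rows.append({"class": labels.name_of(int(label)),
                     "mean_lst_c": float(lst.values[sel].mean()),
                     "mean_ndvi": float(ndvi.values[sel].mean()),
                     "n_pixels": n})
    return pd.DataFrame(rows)


def sample_class_points(labels: LabelMap, n_per_class: int, seed: int
                        ) -> pd.DataFrame:
    """Draw n distinct pixels per class, uniformly without replacement.

    Returns a DataFrame with columns ``row``, ``col``, ``label``;
    deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ArgumentError("n_per_class must be at least 1")
    rng = np.random.default_rng(seed)
    rows = []
    present = np.unique(labels.labels)
    for label in present[present != NODATA_LABEL]:
        rr, cc = np.nonzero(labels.labels == label)
        if rr.size < n_per_class:
            raise ArgumentError(
                f"class {labels.name_of(int(label))!r} has only {rr.size} "
                f"pixels; cannot sample {n_per_class}")
        idx = rng.choice(rr.size, size=n_per_class, replace=False)
        for i in idx:
            rows.append({"row": int(rr[i]), "col": int(cc[i]),
                         "label": int(label)})
    return pd.DataFrame(rows)


def fit_lst_ndvi(lst_values, ndvi_values, label: str = "") -> RegressionFit:
    """OLS of LST on NDVI; needs ≥ 3 pairs with nonzero NDVI variance."""
    y = np.asarray(lst_values, dtype=float)
    x = np.asarray(ndvi_values, dtype=float)
    if y.shape != x.shape:
        raise ArgumentError("LST and NDVI value lists differ in length")
    if x.size < 3:
        raise ArgumentError("need at least 3 point pairs")
    if np.ptp(x) == 0:
        raise ArgumentError("NDVI values are all identical; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(label=label, slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue) ** 2,
                         n_points=int(x.size),
                         stderr_slope=float(res.stderr))


def fit_per_class(lst: BandGrid, ndvi: BandGrid, labels: LabelMap,
                  n_per_class: int = 20, seed: int = 0) -> pd.DataFrame:
    """Sample points and fit the LST–NDVI regression for every class."""
    points = sample_class_points(labels, n_per_class, seed)
    rows = []
    for label, grp in points.groupby("label"):
        rr = grp["row"].to_numpy()
        cc = grp["col"].to_numpy()
        ok = ~lst.nodata_mask[rr, cc] & ~ndvi.nodata_mask[rr, cc]
        fit = fit_lst_ndvi(lst.values[rr[ok], cc[ok]],
                           ndvi.values[rr[ok], cc[ok]],
                           label=labels.name_of(int(label)))
        rows.append({"class": fit.label, "slope": fit.slope,
                     "intercept": fit.intercept, "r_squared": fit.r_squared,
                     "n_points": fit.n_points})
    return pd.DataFrame(rows)
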