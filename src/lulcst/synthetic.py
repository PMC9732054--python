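"""Class-structured synthetic scenes with known ground truth.

Real two-date Landsat acquisitions for a study area are rarely
redistributable, so every downstream stage here is exercised on synthetic
scenes built from a small spectral class library.  A scene is generated in
two steps:

1. a **truth map** — contiguous blocky class regions made by painting
   seeded random rectangles over a base class until each class reaches its
   target area fraction;
2. the **bands** — per-pixel optical digital numbers drawn from each
   class's multivariate normal (3 optical bands, ordered NIR, RED, GREEN to
   mirror the false-colour composite used for classification) and thermal
   DNs from a univariate normal, all clipped to the sensor's
   [QcalMin, QcalMax] range.

The default class library covers the six land-cover classes of a tropical
coastal landscape (urbanized, forests, agricultural, bare land, rocks,
water) with band means chosen so that class-mean NDVI is ordered
forests > agricultural > urbanized > bare > rocks > water (water negative,
rocks near zero) and retrieved LST is ordered
urbanized > bare > rocks > agricultural > forests ≈ water — the qualitative
structure observed over rapidly urbanizing tropical islands.  Separability
is a free parameter (``band_sd``), not a calibration to any real scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import NODATA_LABEL, LabelMap
from .errors import ArgumentError
from .raster_io import BandGrid, SceneMeta, landsat5_tm_meta

CLASS_NAMES = ["urbanized", "forests", "agricultural", "bare", "rocks",
               "water"]

#: optical band order in generated scenes
BAND_ORDER = ("nir", "red", "green")


@dataclass
class ClassSpec:
    """Spectral/thermal distribution and target area share of one class."""

    label: str
    band_means: np.ndarray          # per optical band, DN
    band_cov: np.ndarray            # optical covariance, DN²
    thermal_dn_mean: float
    thermal_dn_sd: float
    area_fraction: float

    def __post_init__(self) -> None:
        self.band_means = np.asarray(self.band_means, dtype=float)
        self.band_cov = np.atleast_2d(np.asarray(self.band_cov, dtype=float))
        if not np.allclose(self.band_cov, self.band_cov.T):
            raise ArgumentError("band_cov must be symmetric")
        if np.linalg.eigvalsh(self.band_cov).min() < -1e-9:
            raise ArgumentError("band_cov must be positive semi-definite")
        if self.thermal_dn_sd < 0:
            raise ArgumentError("thermal_dn_sd must be nonnegative")
        if not 0 <= self.area_fraction <= 1:
            raise ArgumentError("area_fraction must lie in [0, 1]")


@dataclass
class SyntheticScene:
    """Generated bands plus the truth map and metadata that produced them."""

    optical_bands: list[BandGrid]
    thermal_band: BandGrid
    truth_map: LabelMap
    meta: SceneMeta
    seed: int

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.optical_bands}
        shapes |= {self.thermal_band.shape, self.truth_map.shape}
        if len(shapes) != 1:
            raise ArgumentError("all scene grids must share one shape")

    @property
    def nir(self) -> BandGrid:
        return self.optical_bands[0]

    @property
    def red(self) -> BandGrid:
        return self.optical_bands[1]


# (NIR, RED, GREEN) DN means per class.  NDVI class means work out to
# ≈ {forests 0.56, agricultural 0.40, urbanized 0.05, bare 0.02, rocks 0.0,
# water −0.40}; thermal DN means set the LST ordering.
_DEFAULT_MEANS = {
    "urbanized": (105.0, 95.0, 100.0),
    "forests": (140.0, 40.0, 50.0),
    "agricultural": (140.0, 60.0, 80.0),
    "bare": (153.0, 147.0, 120.0),
    "rocks": (90.0, 90.0, 60.0),
    "water": (30.0, 70.0, 50.0),
}
_DEFAULT_THERMAL = {
    "urbanized": 185.0, "bare": 175.0, "rocks": 160.0,
    "agricultural": 145.0, "forests": 135.0, "water": 134.0,
}
#: target area fractions for a two-date run (change-over-time scenario)
DEFAULT_FRACTIONS_T1 = {"urbanized": 0.199, "forests": 0.392,
                        "agricultural": 0.341, "bare": 0.014,
                        "rocks": 0.049, "water": 0.005}
DEFAULT_FRACTIONS_T2 = {"urbanized": 0.290, "forests": 0.398,
                        "agricultural": 0.227, "bare": 0.049,
                        "rocks": 0.024, "water": 0.012}


def default_class_specs(fractions: dict[str, float] | None = None,
                        band_sd: float = 5.0,
                        thermal_sd: float = 3.0) -> list[ClassSpec]:
    """The built-in six-class spectral library.

    ``band_sd`` scales within-class spread in every optical band (spherical
    covariance); the default keeps neighbouring classes ≥ 6 standard
    deviations apart, so maximum-likelihood classification is near-perfect.
    ``fractions`` overrides the per-class area shares (must sum to 1).
    """
    fractions = dict(DEFAULT_FRACTIONS_T1 if fractions is None else fractions)
    missing = set(CLASS_NAMES) - set(fractions)
    if missing:
        raise ArgumentError(f"fractions missing classes: {sorted(missing)}")
    specs = []
    for name in CLASS_NAMES:
        specs.append(ClassSpec(
            label=name,
            band_means=np.array(_DEFAULT_MEANS[name]),
            band_cov=band_sd**2 * np.eye(3),
            thermal_dn_mean=_DEFAULT_THERMAL[name],
            thermal_dn_sd=thermal_sd,
            area_fraction=fractions[name],
        ))
    return specs


def _check_fractions(specs: list[ClassSpec]) -> None:
    total = sum(s.area_fraction for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ArgumentError(f"area fractions sum to {total}, expected 1")


def generate_truth_map(shape: tuple[int, int], specs: list[ClassSpec],
                       region_scale: int = 16, seed: int = 0) -> LabelMap:
    """Blocky truth map whose class fractions match the ClassSpec targets.

    The class with the largest target fraction forms the background; the
    others are painted as seeded random rectangles (side lengths around
    *region_scale*) that only overwrite background pixels, stopping exactly
    at each class's target pixel count.  Realized fractions therefore match
    the targets to within one pixel wherever the background has room.
    """
    rows, cols = shape
    if region_scale < 1 or region_scale > min(rows, cols):
        raise ArgumentError("region_scale must be in [1, min(shape)]")
    _check_fractions(specs)
    rng = np.random.default_rng(seed)
    names = [s.label for s in specs]
    order = np.argsort([-s.area_fraction for s in specs], kind="stable")
    base_idx = int(order[0])
    labels = np.full(shape, base_idx, dtype=np.int64)
    total_px = rows * cols

    for idx in order[1:]:
        spec = specs[idx]
        target = int(round(spec.area_fraction * total_px))
        painted = 0
        attempts = 0
        while painted < target and attempts < 100_000:
            attempts += 1
            h = int(rng.integers(max(1, region_scale // 2),
                                 region_scale + region_scale // 2 + 1))
            w = int(rng.integers(max(1, region_scale // 2),
                                 region_scale + region_scale // 2 + 1))
            r0 = int(rng.integers(0, max(1, rows - h + 1)))
            c0 = int(rng.integers(0, max(1, cols - w + 1)))
            block = labels[r0:r0 + h, c0:c0 + w]
            free = np.flatnonzero(block == base_idx)
            if free.size == 0:
                continue
            take = free[: target - painted]
            block.flat[take] = idx
            painted += take.size
        if painted < target:
            raise ArgumentError(
                f"could not reach target fraction for class {spec.label!r}")
    return LabelMap(labels=labels, class_names=names)


def generate_scene(truth_map: LabelMap, specs: list[ClassSpec],
                   meta: SceneMeta | None = None, seed: int = 0,
                   pixel_size_m: float = 30.0) -> SyntheticScene:
    """Draw optical and thermal DNs for every pixel of a truth map.

    Per-class draws use independent substreams of *seed* in a fixed class
    order, so scenes are bit-reproducible.  All DNs are clipped to the
    sensor's [QcalMin, QcalMax].
    """
    meta = landsat5_tm_meta() if meta is None else meta
    by_label = {s.label: s for s in specs}
    names = truth_map.class_names or [s.label for s in specs]
    present = np.unique(truth_map.labels)
    present = present[present != NODATA_LABEL]
    for idx in present:
        name = names[idx] if idx < len(names) else str(idx)
        if name not in by_label:
            raise ArgumentError(f"truth map label {name!r} has no ClassSpec")

    nbands = len(BAND_ORDER)
    shape = truth_map.shape
    optical = np.empty(shape + (nbands,), dtype=float)
    thermal = np.empty(shape, dtype=float)
    streams = np.random.SeedSequence(seed).spawn(len(names))
    for idx, name in enumerate(names):
        sel = truth_map.labels == idx
        n = int(sel.sum())
        if n == 0:
            continue
        spec = by_label[name]
        rng = np.random.default_rng(streams[idx])
        optical[sel] = rng.multivariate_normal(spec.band_means, spec.band_cov,
                                               size=n)
        thermal[sel] = spec.thermal_dn_mean + \
            spec.thermal_dn_sd * rng.standard_normal(n)

    optical = np.clip(optical, meta.QcalMin, meta.QcalMax)
    thermal = np.clip(thermal, meta.QcalMin, meta.QcalMax)
    bands = [BandGrid(values=optical[..., b], pixel_size_m=pixel_size_m,
                      band_id=BAND_ORDER[b]) for b in range(nbands)]
    tgrid = BandGrid(values=thermal, pixel_size_m=pixel_size_m,
                     band_id="thermal")
    truth = LabelMap(labels=truth_map.labels, pixel_size_m=pixel_size_m,
                     class_names=list(names))
    return SyntheticScene(optical_bands=bands, thermal_band=tgrid,
                          truth_map=truth, meta=meta, seed=seed)


def sample_truth_points(truth_map: LabelMap, n_per_class: int, seed: int
                        ) -> pd.DataFrame:
    """n distinct, truth-labeled pixel coordinates per class (seeded).

    The returned frame has columns ``row``, ``col``, ``label``; labels are
    read off the truth map, emulating ground-truth point collection.
    """
    if n_per_class < 1:
        raise ArgumentError("n_per_class must be at least 1")
    rng = np.random.default_rng(seed)
    records = []
    present = np.unique(truth_map.labels)
    for label in present[present != NODATA_LABEL]:
        rr, cc = np.nonzero(truth_map.labels == label)
        if rr.size < n_per_class:
            raise ArgumentError(
                f"class {truth_map.name_of(int(label))!r} has only "
                f"{rr.size} pixels; cannot sample {n_per_class}")
        idx = rng.choice(rr.size, size=n_per_class, replace=False)
        for i in idx:
            records.append({"row": int(rr[i]), "col": int(cc[i]),
                            "label": int(label)})
    return pd.DataFrame(records)
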