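"""End-to-end two-date analysis: scenes → products → classes → change.

``run_pipeline`` orchestrates the full chain for a pair of dates:

    scene (synthetic or from files)
      → thermal chain (radiance, brightness temperature)
      → surface products (NDVI, PV, emissivity, LST)
      → training-point sampling, signatures, maximum-likelihood map
      → accuracy assessment on held-out points
      → per-class areas; two-date change table
      → per-class LST/NDVI means and LST-on-NDVI regressions

and writes every raster (TIFF) and table (CSV) into an output directory
together with a JSON manifest recording the configuration and seeds.  All
randomness flows from one seed, split into fixed per-stage substreams, so a
rerun with the same configuration reproduces every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy import accuracy_table, build_error_matrix
from .change import change_table, class_areas
from .classify import LabelMap, classify_mlc, extract_signatures
from .errors import ArgumentError, ConfigError
from .radiometry import brightness_temperature, toa_radiance
from .raster_io import (BandGrid, SceneMeta, read_band, read_scene_meta,
                        write_band)
from .surface import (emissivity, land_surface_temperature, ndvi,
                      proportion_vegetation)
from .synthetic import (DEFAULT_FRACTIONS_T1, DEFAULT_FRACTIONS_T2,
                        SyntheticScene, default_class_specs, generate_scene,
                        generate_truth_map, sample_truth_points)
from .zonal import class_means, fit_per_class

log = logging.getLogger(__name__)


@dataclass
class SceneFiles:
    """File-based inputs for one date (alternative to synthesis)."""

    optical_paths: list[str]   # NIR, RED, GREEN order
    thermal_path: str
    meta_path: str
    training_path: str         # CSV row,col,label
    reference_path: str        # CSV row,col,label (held-out accuracy points)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable to YAML.

    Synthetic mode (default) builds the two dates from the built-in class
    library at the given area fractions; file mode reads bands, metadata
    and point sets from ``scene_files``.
    """

    shape: tuple[int, int] = (200, 200)
    fractions_t1: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS_T1))
    fractions_t2: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS_T2))
    interval_years: float = 11.0
    seed: int = 0
    band_sd: float = 5.0
    thermal_sd: float = 3.0
    region_scale: int = 16
    n_train_per_class: int = 40
    n_test_per_class: int = 40
    n_relate_per_class: int = 20
    lst_mode: str = "celsius_literal"
    ndvi_min: float | None = None
    ndvi_max: float | None = None
    priors: dict[int, float] | None = None
    pixel_size_m: float = 30.0
    scene_files: list[SceneFiles] | None = None
    out_dir: str = "lulcst_run"

    def __post_init__(self) -> None:
        if not self.interval_years > 0:
            raise ConfigError("interval_years must be positive")
        for name in ("n_train_per_class", "n_test_per_class",
                     "n_relate_per_class"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be at least 1")
        if self.scene_files is not None and len(self.scene_files) != 2:
            raise ConfigError("scene_files must list exactly two dates")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        if raw.get("scene_files"):
            raw["scene_files"] = [SceneFiles(**sf) for sf in raw["scene_files"]]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        return d


def _sub_seed(root: int, stage: str, date: int = 0) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    tag = zlib.crc32(stage.encode()) % (2**31)
    h = np.random.SeedSequence([root, date, tag])
    return int(h.generate_state(1)[0] % (2**31))


def _load_scene_files(sf: SceneFiles, pixel_size_m: float):
    bands = [read_band(p) for p in sf.optical_paths]
    thermal = read_band(sf.thermal_path)
    meta = read_scene_meta(sf.meta_path)
    train = pd.read_csv(sf.training_path)
    ref = pd.read_csv(sf.reference_path)
    return bands, thermal, meta, train, ref, None


def _build_synthetic(config: RunConfig, date: int):
    fractions = config.fractions_t1 if date == 0 else config.fractions_t2
    specs = default_class_specs(fractions=fractions, band_sd=config.band_sd,
                                thermal_sd=config.thermal_sd)
    truth = generate_truth_map(config.shape, specs,
                               region_scale=config.region_scale,
                               seed=_sub_seed(config.seed, "truth", date))
    scene = generate_scene(truth, specs,
                           seed=_sub_seed(config.seed, "scene", date),
                           pixel_size_m=config.pixel_size_m)
    train = sample_truth_points(truth, config.n_train_per_class,
                                seed=_sub_seed(config.seed, "train", date))
    ref = sample_truth_points(truth, config.n_test_per_class,
                              seed=_sub_seed(config.seed, "test", date))
    return (scene.optical_bands, scene.thermal_band, scene.meta, train, ref,
            scene.truth_map)


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return str(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full two-date analysis; returns the manifest dict.

    The manifest lists every produced artifact and echoes the configuration
    and package version; it is also written to ``<out_dir>/manifest.json``.
    On any stage failure a ``FAILED`` marker file naming the stage is left
    in the output directory before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "version": __version__,
                      "outputs": {}}
    stage = "setup"
    try:
        per_date = []
        for date in (0, 1):
            stage = f"scene[date{date + 1}]"
            ddir = out / f"date{date + 1}"
            ddir.mkdir(exist_ok=True)
            if config.scene_files is not None:
                bands, thermal, meta, train, ref, truth = _load_scene_files(
                    config.scene_files[date], config.pixel_size_m)
            else:
                bands, thermal, meta, train, ref, truth = _build_synthetic(
                    config, date)
            arts: dict = {}

            stage = f"radiometry[date{date + 1}]"
            radiance = toa_radiance(thermal, meta)
            bt = brightness_temperature(radiance, meta)

            stage = f"products[date{date + 1}]"
            nir, red = bands[0], bands[1]
            ndvi_grid = ndvi(red, nir)
            pv = proportion_vegetation(ndvi_grid, config.ndvi_min,
                                       config.ndvi_max)
            emis = emissivity(pv)
            lst = land_surface_temperature(bt, emis, meta,
                                           bt_scale=config.lst_mode)
            for name, grid in [("radiance", radiance), ("bt", bt),
                               ("ndvi", ndvi_grid), ("pv", pv),
                               ("emissivity", emis), ("lst", lst)]:
                arts[name] = str(write_band(grid, ddir / f"{name}.tif"))

            stage = f"classify[date{date + 1}]"
            names = truth.class_names if truth is not None else \
                sorted(train["label"].astype(str).unique())
            sigs = extract_signatures(bands, train, class_names=names)
            lulc = classify_mlc(bands, sigs, priors=config.priors,
                                class_names=names)
            arts["lulc"] = str(write_band(
                BandGrid(values=lulc.labels,
                         pixel_size_m=config.pixel_size_m, band_id="lulc"),
                ddir / "lulc.tif", nodata=-1))
            (ddir / "classes.json").write_text(json.dumps(
                {i: n for i, n in enumerate(names)}, indent=1))

            stage = f"assess[date{date + 1}]"
            em = build_error_matrix(lulc, ref, n_classes=len(names))
            arts["error_matrix"] = _write_csv(em.to_dataframe().reset_index(),
                                              ddir / "error_matrix.csv")
            arts["accuracy"] = _write_csv(accuracy_table(em),
                                          ddir / "accuracy.csv")

            stage = f"areas[date{date + 1}]"
            areas = class_areas(lulc)
            arts["areas"] = _write_csv(areas.to_dataframe(),
                                       ddir / "areas.csv")

            stage = f"relate[date{date + 1}]"
            arts["zonal_means"] = _write_csv(
                class_means(lst, ndvi_grid, lulc), ddir / "zonal_means.csv")
            arts["regression"] = _write_csv(
                fit_per_class(lst, ndvi_grid, lulc,
                              n_per_class=config.n_relate_per_class,
                              seed=_sub_seed(config.seed, "relate", date)),
                ddir / "lst_ndvi_regression.csv")

            manifest["outputs"][f"date{date + 1}"] = arts
            per_date.append({"areas": areas, "lulc": lulc})

        stage = "change"
        chg = change_table(per_date[0]["areas"], per_date[1]["areas"],
                           interval_years=config.interval_years)
        manifest["outputs"]["change"] = _write_csv(chg, out / "change.csv")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    manifest["manifest_path"] = str(out / "manifest.json")
    return manifest
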