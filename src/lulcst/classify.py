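"""Gaussian maximum-likelihood land-cover classification.

Each class is summarized by the sample mean vector and sample covariance
matrix of its training pixels in band space (the classic "signature").  A
pixel x is assigned to the class maximizing the quadratic discriminant

    gᵢ(x) = ln pᵢ − ½ ln|Σᵢ| − ½ (x − μᵢ)ᵀ Σᵢ⁻¹ (x − μᵢ),

i.e. the log of the class-conditional multivariate normal density times the
prior pᵢ.  Priors are equal unless supplied.  Ties go to the lowest class
index; pixels with nodata in any band stay nodata.

Covariances from small or degenerate training sets are regularized by
adding ε to the diagonal whenever the smallest eigenvalue falls below ε,
with ε = 1e-6 × the mean diagonal entry (floored at 1e-6 when the diagonal
is all zero, as happens with identical training pixels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, NumericalError
from .raster_io import BandGrid

log = logging.getLogger(__name__)

NODATA_LABEL = -1


@dataclass
class LabelMap:
    """Per-pixel class raster; label −1 marks nodata."""

    labels: np.ndarray
    pixel_size_m: float = 30.0
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ArgumentError("label map must be 2-D")
        if not self.pixel_size_m > 0:
            raise ArgumentError("pixel_size_m must be positive")
        if self.class_names:
            valid = (self.labels == NODATA_LABEL) | (
                (self.labels >= 0) & (self.labels < len(self.class_names)))
            if not valid.all():
                raise ArgumentError("label outside the class_names range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def name_of(self, index: int) -> str:
        if self.class_names and 0 <= index < len(self.class_names):
            return self.class_names[index]
        return str(index)


@dataclass
class ClassSignature:
    """Training statistics for one class."""

    label: int
    mean: np.ndarray
    covariance: np.ndarray
    n_train: int
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ArgumentError("covariance shape inconsistent with mean")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ArgumentError("covariance must be symmetric")


def _regularize(cov: np.ndarray) -> tuple[np.ndarray, float]:
    mean_diag = float(np.trace(cov)) / cov.shape[0]
    eps = 1e-6 * mean_diag if mean_diag > 0 else 1e-6
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < eps:
        return cov + eps * np.eye(cov.shape[0]), eps
    return cov, 0.0


def _stack_bands(bands: list[BandGrid]) -> tuple[np.ndarray, np.ndarray]:
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise ArgumentError("bands must share one shape")
    cube = np.stack([b.values.astype(float) for b in bands], axis=-1)
    nodata = np.any(np.stack([b.nodata_mask for b in bands]), axis=0)
    return cube, nodata


def extract_signatures(bands: list[BandGrid], training: pd.DataFrame,
                       class_names: list[str] | None = None
                       ) -> list[ClassSignature]:
    """Per-class mean and covariance of band values at labeled points.

    *training* needs columns ``row``, ``col``, ``label`` (integer class
    index, or name resolvable through *class_names*).  Points on nodata
    pixels are skipped with a logged count.  Each class needs at least
    band-count + 1 usable points.
    """
    cube, nodata = _stack_bands(bands)
    nbands = cube.shape[-1]
    df = training.copy()
    if class_names and df["label"].dtype == object:
        df["label"] = df["label"].map({n: i for i, n in enumerate(class_names)})
    rows = df["row"].to_numpy(dtype=int)
    cols = df["col"].to_numpy(dtype=int)
    on_nodata = nodata[rows, cols]
    if on_nodata.any():
        log.warning("skipped %d training points on nodata pixels",
                    int(on_nodata.sum()))
    rows, cols = rows[~on_nodata], cols[~on_nodata]
    labels = df["label"].to_numpy(dtype=int)[~on_nodata]

    signatures = []
    for label in np.unique(labels):
        sel = labels == label
        n = int(sel.sum())
        if n < nbands + 1:
            name = class_names[label] if class_names else str(label)
            raise ArgumentError(
                f"class {name!r} has {n} usable training points; "
                f"need at least {nbands + 1}")
        x = cube[rows[sel], cols[sel], :]
        cov = np.cov(x, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        cov, eps = _regularize(cov)
        signatures.append(ClassSignature(label=int(label), mean=x.mean(axis=0),
                                         covariance=cov, n_train=n,
                                         regularization=eps))
    return signatures


def classify_mlc(bands: list[BandGrid], signatures: list[ClassSignature],
                 priors: dict[int, float] | None = None,
                 class_names: list[str] | None = None) -> LabelMap:
    """Assign each pixel to the class with the highest Gaussian likelihood.

    Equal priors by default; if *priors* maps class label → probability it
    must sum to 1.  Ties break to the lowest class index; nodata in any
    input band propagates.
    """
    if len(signatures) < 2:
        raise ArgumentError("need signatures for at least 2 classes")
    cube, nodata = _stack_bands(bands)
    h, w, nb = cube.shape
    x = cube.reshape(-1, nb)

    sigs = sorted(signatures, key=lambda s: s.label)
    if priors is not None:
        total = sum(priors.get(s.label, 0.0) for s in sigs)
        if abs(total - 1.0) > 1e-9:
            raise ArgumentError("priors must sum to 1 over the signature set")

    scores = np.full((x.shape[0], len(sigs)), -np.inf)
    for j, sig in enumerate(sigs):
        sign, logdet = np.linalg.slogdet(sig.covariance)
        if sign <= 0:
            raise NumericalError(
                f"singular covariance for class {sig.label} "
                "after regularization")
        p = 1.0 / len(sigs) if priors is None else priors.get(sig.label, 0.0)
        if p <= 0:
            continue
        diff = x - sig.mean
        sol = np.linalg.solve(sig.covariance, diff.T)
        maha = np.einsum("ij,ji->i", diff, sol)
        scores[:, j] = np.log(p) - 0.5 * logdet - 0.5 * maha

    best = np.argmax(scores, axis=1)  # first max → lowest class index
    labels = np.array([s.label for s in sigs])[best].reshape(h, w)
    labels[nodata] = NODATA_LABEL
    return LabelMap(labels=labels, pixel_size_m=bands[0].pixel_size_m,
                    class_names=class_names or [])
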