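"""Error-matrix accuracy assessment for classified maps.

Convention used throughout: **rows are predicted classes, columns are
reference (ground-truth) classes**.  Producer's accuracy for class k is the
diagonal count over the reference-column total (100% − omission error);
user's accuracy is the diagonal count over the predicted-row total
(100% − commission error).  Overall accuracy is trace/total, and Cohen's
kappa is the chance-corrected agreement (pₒ − pₑ)/(1 − pₑ) with
pₑ = Σₖ rowₖ·colₖ / total².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import NODATA_LABEL, LabelMap
from .errors import ArgumentError

log = logging.getLogger(__name__)


@dataclass
class ErrorMatrix:
    """K×K count cross-tabulation; rows = predicted, columns = reference."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ArgumentError("error matrix must be square")
        if (self.counts < 0).any():
            raise ArgumentError("error-matrix counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ArgumentError("error matrix is empty")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        names = self.class_names or [str(i) for i in range(self.n_classes)]
        return pd.DataFrame(self.counts, index=pd.Index(names, name="predicted"),
                            columns=pd.Index(names, name="reference"))


def build_error_matrix(predicted: LabelMap, reference: pd.DataFrame,
                       n_classes: int | None = None) -> ErrorMatrix:
    """Cross-tabulate predicted labels against reference points.

    *reference* needs columns ``row``, ``col``, ``label``.  Points falling
    on nodata predicted pixels are skipped with a logged count.
    """
    if len(reference) == 0:
        raise ArgumentError("reference point set is empty")
    rows = reference["row"].to_numpy(dtype=int)
    cols = reference["col"].to_numpy(dtype=int)
    ref = reference["label"].to_numpy(dtype=int)
    pred = predicted.labels[rows, cols]
    on_nodata = pred == NODATA_LABEL
    if on_nodata.any():
        log.warning("skipped %d reference points on nodata pixels",
                    int(on_nodata.sum()))
    pred, ref = pred[~on_nodata], ref[~on_nodata]
    if pred.size == 0:
        raise ArgumentError("no reference points on classified pixels")
    k = n_classes or max(len(predicted.class_names),
                         int(max(pred.max(), ref.max())) + 1)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (pred, ref), 1)
    return ErrorMatrix(counts=counts, class_names=predicted.class_names)


def producers_accuracy(m: ErrorMatrix) -> np.ndarray:
    """Per-class producer's accuracy (%); NaN where the reference column
    is empty."""
    col = m.counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * np.diag(m.counts) / col
    return np.where(col > 0, out, np.nan)


def users_accuracy(m: ErrorMatrix) -> np.ndarray:
    """Per-class user's accuracy (%); NaN where the predicted row is
    empty."""
    row = m.counts.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * np.diag(m.counts) / row
    return np.where(row > 0, out, np.nan)


def overall_accuracy(m: ErrorMatrix) -> float:
    """Overall accuracy (%): correctly classified over total sampled."""
    return 100.0 * float(np.trace(m.counts)) / float(m.counts.sum())


def kappa(m: ErrorMatrix) -> float:
    """Cohen's kappa; NaN when expected agreement is 1 (degenerate)."""
    total = float(m.counts.sum())
    po = float(np.trace(m.counts)) / total
    pe = float(m.counts.sum(axis=1) @ m.counts.sum(axis=0)) / total**2
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def accuracy_table(m: ErrorMatrix) -> pd.DataFrame:
    """Per-class producer's/user's accuracy plus overall accuracy and kappa.

    Values are full precision; round at presentation time.
    """
    names = m.class_names or [str(i) for i in range(m.n_classes)]
    df = pd.DataFrame({
        "class": names,
        "producers_accuracy_pct": producers_accuracy(m),
        "users_accuracy_pct": users_accuracy(m),
    })
    df["overall_accuracy_pct"] = overall_accuracy(m)
    df["kappa"] = kappa(m)
    return df
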