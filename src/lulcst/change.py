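"""Per-class area tabulation and two-date change statistics.

Areas come straight from pixel counts: area_ha = count × pixel_size² / 10⁴.
Change between two dates follows the standard post-classification bookkeeping

    changed area   Ca = A(t2) − A(t1)            [ha]
    changed extent Ce = Ca / A(t1)               [dimensionless]
    percent change    = 100 · Ce                 [%]
    annual rate       = percent change / Δt      [% per year]

The annual rate is the simple (linear) rate; a compound alternative
((A2/A1)^(1/Δt) − 1)·100 is available via ``compound=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import NODATA_LABEL, LabelMap
from .errors import ArgumentError

M2_PER_HA = 10_000.0


@dataclass
class AreaTable:
    """Per-class areas (ha and % of the mapped total) for one date."""

    areas_ha: dict[str, float]
    total_area_ha: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.areas_ha:
            raise ArgumentError("area table has no classes")
        if any(a < 0 for a in self.areas_ha.values()):
            raise ArgumentError("areas must be nonnegative")
        self.total_area_ha = float(sum(self.areas_ha.values()))

    @property
    def percentages(self) -> dict[str, float]:
        return {c: 100.0 * a / self.total_area_ha
                for c, a in self.areas_ha.items()}

    def to_dataframe(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame({
            "class": list(self.areas_ha),
            "area_ha": list(self.areas_ha.values()),
            "area_pct": [pct[c] for c in self.areas_ha],
        })


def class_areas(labels: LabelMap) -> AreaTable:
    """Tabulate per-class area from a label map.

    Percentages are relative to the non-nodata total.  Classes listed in
    ``class_names`` but absent from the map get zero area.
    """
    px_ha = labels.pixel_size_m**2 / M2_PER_HA
    flat = labels.labels[labels.labels != NODATA_LABEL]
    if flat.size == 0:
        raise ArgumentError("label map is entirely nodata")
    n_classes = max(len(labels.class_names), int(flat.max()) + 1)
    counts = np.bincount(flat, minlength=n_classes)
    return AreaTable(areas_ha={labels.name_of(i): float(counts[i] * px_ha)
                               for i in range(n_classes)})


def change_table(t1: AreaTable, t2: AreaTable, interval_years: float,
                 compound: bool = False) -> pd.DataFrame:
    """Two-date per-class change statistics.

    Classes with zero area at the first date get NaN for the relative
    measures (extent, percent, annual rate); the absolute change is still
    reported.
    """
    if not interval_years > 0:
        raise ArgumentError("interval_years must be positive")
    if set(t1.areas_ha) != set(t2.areas_ha):
        raise ArgumentError("the two area tables cover different class sets")
    rows = []
    for cls in t1.areas_ha:
        a1, a2 = t1.areas_ha[cls], t2.areas_ha[cls]
        ca = a2 - a1
        if a1 > 0:
            ce = ca / a1
            pct = 100.0 * ce
            if compound:
                annual = ((a2 / a1) ** (1.0 / interval_years) - 1.0) * 100.0 \
                    if a2 > 0 else float("nan")
            else:
                annual = pct / interval_years
        else:
            ce = pct = annual = float("nan")
        rows.append({"class": cls, "area_t1_ha": a1, "area_t2_ha": a2,
                     "change_ha": ca, "change_extent": ce,
                     "pct_change": pct, "annual_rate_pct": annual,
                     "interval_years": interval_years})
    return pd.DataFrame(rows)
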