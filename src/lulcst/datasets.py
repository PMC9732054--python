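"""Small bundled reference tables used by the examples and tests."""

from __future__ import annotations

import pandas as pd

from .change import AreaTable

# Published two-date LULC area tabulation (hectares) for Penang Island,
# Malaysia — classified Landsat scenes from 2010 and 2021 at 30 m.  Used as
# the worked example for the change statistics.
_PENANG_AREAS_HA = {
    "class": ["urbanized", "forests", "agricultural", "bare", "rocks",
              "water"],
    2010: [6111.62, 12025.44, 10456.32, 425.44, 1495.07, 189.12],
    2021: [8905.43, 12213.70, 6954.51, 1521.21, 722.89, 385.27],
}

PENANG_INTERVAL_YEARS = 11.0


def penang_island_areas() -> pd.DataFrame:
    """Per-class areas (ha) of Penang Island in 2010 and 2021."""
    return pd.DataFrame(_PENANG_AREAS_HA).set_index("class")


def penang_area_tables() -> tuple[AreaTable, AreaTable]:
    """The same tabulation as a pair of :class:`~lulcst.change.AreaTable`."""
    df = penang_island_areas()
    return (AreaTable(areas_ha=df[2010].to_dict()),
            AreaTable(areas_ha=df[2021].to_dict()))
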