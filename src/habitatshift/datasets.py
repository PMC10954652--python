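"""Bundled study tables: published per-class land-cover areas and
per-class resource moments for the Mexico and Texas study extents.

The Mexico extent uses an 8-class GLAD-derived legend over 2000–2020; the
Texas extent uses a 15-class NLCD-derived legend over 2001–2019. The
resource tables hold the per-class means and SDs of the modelled
fall/spring nectar scores (unitless, 0–1) and milkweed values (a unitless
expert index in Mexico; plants/ha in Texas). Classes with no resource
(open water; for Texas milkweed also barren, crops and wetlands) carry
zeros.

Note on annualization: the published Mexico "annual change" column divides
net change by 19 although the interval is 2000–2020; the Texas column
divides by 18 (2001–2019). ``REGIONS`` records the divisor each published
table used so the accounting reproduces the printed columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _res

import pandas as pd

__all__ = ["REGIONS", "RegionInfo", "load_change_table", "load_resource_table",
           "milkweed_units"]


@dataclass(frozen=True)
class RegionInfo:
    name: str
    start_year: int
    end_year: int
    annualization_years: int  # divisor the published table used
    milkweed_units: str


REGIONS = {
    "mexico": RegionInfo("mexico", 2000, 2020, 19, "score"),
    "texas": RegionInfo("texas", 2001, 2019, 18, "plants_per_ha"),
}


def _read(name: str) -> pd.DataFrame:
    with _res.files("habitatshift.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_change_table(region: str) -> pd.DataFrame:
    """Per-class start/end areas and loss/gain (km²) for a study extent."""
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}; choose from {sorted(REGIONS)}")
    return _read(f"landcover_change_{region}.csv").set_index("class")


def load_resource_table(region: str) -> pd.DataFrame:
    """Per-class resource means/SDs (nectar scores; milkweed values)."""
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}; choose from {sorted(REGIONS)}")
    return _read(f"resource_values_{region}.csv")


def milkweed_units(region: str) -> str:
    return REGIONS[region].milkweed_units
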