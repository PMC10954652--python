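"""Grid and table I/O.

Land-cover and zone grids are read from single-band integer TIFFs (via
tifffile) or from plain CSV lattices; the per-cell area in km² comes from
the caller or a run config — grids must be pre-aligned, and no projection
metadata is interpreted. Area tables and outputs are CSV throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .change import ClassScheme, LandcoverGrid

__all__ = ["read_grid", "write_grid", "read_area_table", "write_zone_geojson"]


def _read_lattice(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
        if arr.ndim != 2:
            raise ValueError(f"{path} is not a single-band raster (shape {arr.shape})")
        return arr.astype(np.int64)
    return np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)


def read_grid(
    path: str | Path,
    cell_area: float,
    scheme: ClassScheme | None = None,
    zones_path: str | Path | None = None,
    nodata_code: int = -1,
) -> LandcoverGrid:
    """Load a categorical land-cover grid (TIFF or CSV lattice).

    Without an explicit scheme, one is inferred from the codes present.
    """
    values = _read_lattice(path)
    if scheme is None:
        ids = sorted(int(v) for v in np.unique(values) if v != nodata_code)
        scheme = ClassScheme("inferred", tuple((i, str(i)) for i in ids), nodata_code)
    zones = _read_lattice(zones_path) if zones_path is not None else None
    return LandcoverGrid(values, cell_area, scheme, zones)


def write_grid(path: str | Path, grid: LandcoverGrid) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, grid.values.astype(np.int32))
    else:
        np.savetxt(path, grid.values, fmt="%d", delimiter=",")


def read_area_table(path: str | Path) -> pd.DataFrame:
    """Per-class two-date area table: class_id, start_area_km2, end_area_km2."""
    df = pd.read_csv(path)
    required = {"class_id", "start_area_km2", "end_area_km2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"area table missing columns {sorted(missing)}")
    return df.set_index("class_id")


def write_zone_geojson(path: str | Path, zone_table: pd.DataFrame) -> None:
    """Property-only GeoJSON join on zone id (no geometry is synthesized)."""
    features = [
        {"type": "Feature", "geometry": None,
         "properties": {"zone": z, **{k: (None if pd.isna(v) else v)
                                      for k, v in row.items()}}}
        for z, row in zone_table.iterrows()
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))
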