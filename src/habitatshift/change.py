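"""Land-cover transition accounting.

Compares two categorical land-cover grids (or published per-class area
tables) over one interval and tabulates the areal flows between classes,
per-class gain/loss/net/gross statistics, and per-zone summaries. The
accounting conventions follow standard land-change analysis: net change is
gain minus loss, gross change is gain plus loss, and annual change is net
change divided by the interval length in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassScheme",
    "LandcoverGrid",
    "TransitionMatrix",
    "compute_transition_matrix",
    "summarize_change",
    "change_summary_from_components",
    "zonal_change",
    "transitions_long",
    "transitions_from_long",
]


@dataclass(frozen=True)
class ClassScheme:
    """A categorical land-cover legend: integer codes with labels."""

    scheme_id: str
    classes: tuple[tuple[int, str], ...]
    nodata_code: int = -1

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("class codes must be unique")
        if self.nodata_code in ids:
            raise ValueError("nodata code collides with a class code")

    @property
    def class_ids(self) -> list[int]:
        return [c for c, _ in self.classes]

    @property
    def labels(self) -> dict[int, str]:
        return dict(self.classes)

    @classmethod
    def from_labels(cls, scheme_id: str, labels: list[str], nodata_code: int = -1) -> "ClassScheme":
        return cls(scheme_id, tuple(enumerate(labels)), nodata_code)


@dataclass
class LandcoverGrid:
    """A single-date categorical raster with a fixed per-cell area (km²).

    Georeferencing is deliberately not interpreted: grids must be
    pre-aligned, and ``cell_area`` carries all spatial weighting. An
    optional shape-identical ``zones`` lattice assigns each cell to an
    administrative unit (county / municipality) for zonal summaries.
    """

    values: np.ndarray
    cell_area: float
    scheme: ClassScheme
    zones: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("land-cover grid must hold integer class codes")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        valid = self.values != self.scheme.nodata_code
        known = np.isin(self.values[valid], self.scheme.class_ids)
        if not known.all():
            bad = np.unique(self.values[valid][~known])
            raise ValueError(f"codes {bad.tolist()} not in scheme {self.scheme.scheme_id!r}")
        if self.zones is not None:
            self.zones = np.asarray(self.zones)
            if self.zones.shape != self.values.shape:
                raise ValueError("zone lattice must match grid shape")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.scheme.nodata_code


@dataclass
class TransitionMatrix:
    """Areal flows (km²) between classes over one interval.

    ``area.loc[i, j]`` is the area that was class ``i`` at the start date
    and class ``j`` at the end date; the diagonal is persistence. Row sums
    are start-date class areas, column sums end-date class areas.
    """

    area: pd.DataFrame
    start_year: int
    end_year: int
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.area.values < -1e-9).any():
            raise ValueError("transition areas must be nonnegative")
        if list(self.area.index) != list(self.area.columns):
            raise ValueError("transition matrix must be square over one class set")

    @property
    def start_areas(self) -> pd.Series:
        return self.area.sum(axis=1)

    @property
    def end_areas(self) -> pd.Series:
        return self.area.sum(axis=0)

    @property
    def total_area(self) -> float:
        return float(self.area.values.sum())

    def __add__(self, other: "TransitionMatrix") -> "TransitionMatrix":
        if (self.start_year, self.end_year) != (other.start_year, other.end_year):
            raise ValueError("interval mismatch")
        return TransitionMatrix(self.area.add(other.area, fill_value=0.0),
                                self.start_year, self.end_year, self.labels)


def _check_pair(grid_t0: LandcoverGrid, grid_t1: LandcoverGrid) -> None:
    if grid_t0.values.shape != grid_t1.values.shape:
        raise ValueError(
            f"grid shapes differ: {grid_t0.values.shape} vs {grid_t1.values.shape}")
    if grid_t0.scheme.scheme_id != grid_t1.scheme.scheme_id or \
            grid_t0.scheme.classes != grid_t1.scheme.classes:
        raise ValueError("grids use different class schemes")
    if grid_t0.cell_area != grid_t1.cell_area:
        raise ValueError("grids have different cell areas")


def compute_transition_matrix(
    grid_t0: LandcoverGrid,
    grid_t1: LandcoverGrid,
    start_year: int = 0,
    end_year: int = 0,
) -> TransitionMatrix:
    """Cross-tabulate two dates of one landscape into areal flows.

    A cell contributes ``cell_area`` to entry (i, j) when it is class i at
    the start date and class j at the end date. Cells that are nodata at
    either date are excluded, which keeps both marginals defined on the
    same valid footprint.
    """
    _check_pair(grid_t0, grid_t1)
    ids = grid_t0.scheme.class_ids
    mask = grid_t0.valid_mask & grid_t1.valid_mask
    if not mask.any():
        raise ValueError("no cell is valid at both dates; transition matrix is empty")
    code_to_pos = np.full(max(ids) + 1, -1, dtype=np.int64)
    code_to_pos[np.array(ids)] = np.arange(len(ids))
    i = code_to_pos[grid_t0.values[mask]]
    j = code_to_pos[grid_t1.values[mask]]
    k = len(ids)
    counts = np.bincount(i * k + j, minlength=k * k).reshape(k, k)
    area = pd.DataFrame(counts * grid_t0.cell_area, index=ids, columns=ids, dtype=float)
    return TransitionMatrix(area, start_year, end_year, grid_t0.scheme.labels)


def change_summary_from_components(
    start_area: pd.Series,
    end_area: pd.Series,
    loss: pd.Series,
    gain: pd.Series,
    interval_years: int,
) -> pd.DataFrame:
    """Per-class change statistics from start/end areas and gain/loss.

    net = gain − loss; gross = gain + loss; annual = net / interval_years;
    percent_total = 100·net/start_area (missing, not 0, when a class has no
    start-date area); percent_annual = percent_total / interval_years.
    """
    if interval_years <= 0:
        raise ValueError("interval_years must be positive")
    net = gain - loss
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_total = 100.0 * net / start_area.replace(0.0, np.nan)
    out = pd.DataFrame({
        "start_area": start_area,
        "end_area": end_area,
        "loss": loss,
        "gain": gain,
        "net": net,
        "gross": gain + loss,
        "annual": net / interval_years,
        "percent_annual": pct_total / interval_years,
        "percent_total": pct_total,
    })
    return out.rename_axis("class")


def summarize_change(tm: TransitionMatrix, interval_years: int | None = None) -> pd.DataFrame:
    """Reduce a transition matrix to per-class change statistics.

    Loss of class i is its start area minus its persistence (diagonal);
    gain of class j is its end area minus persistence. ``interval_years``
    defaults to ``end_year − start_year``.
    """
    if interval_years is None:
        interval_years = tm.end_year - tm.start_year
    diag = pd.Series(np.diag(tm.area.values), index=tm.area.index)
    return change_summary_from_components(
        tm.start_areas, tm.end_areas, tm.start_areas - diag, tm.end_areas - diag,
        interval_years)


def zonal_change(
    grid_t0: LandcoverGrid,
    grid_t1: LandcoverGrid,
    start_year: int = 0,
    end_year: int = 0,
    interval_years: int | None = None,
) -> tuple[dict[int, TransitionMatrix], pd.DataFrame]:
    """Per-zone transition matrices and change summaries.

    Returns the matrices keyed by zone id and a tidy table of per-zone
    per-class statistics plus each zone's percent total gross change
    (changed-area fraction of the zone, on the 0–100 scale, counting each
    converted cell once). Zonal matrices sum exactly to the extent matrix.
    """
    _check_pair(grid_t0, grid_t1)
    if grid_t0.zones is None:
        raise ValueError("zonal_change requires a zone lattice on the start-date grid")
    if grid_t1.zones is not None and not np.array_equal(grid_t0.zones, grid_t1.zones):
        raise ValueError("zone lattices differ between dates")
    if interval_years is None:
        interval_years = end_year - start_year
    if interval_years <= 0:
        interval_years = 1
    matrices: dict[int, TransitionMatrix] = {}
    rows = []
    for zone in np.unique(grid_t0.zones):
        zmask = grid_t0.zones == zone
        sub0 = LandcoverGrid(
            np.where(zmask, grid_t0.values, grid_t0.scheme.nodata_code),
            grid_t0.cell_area, grid_t0.scheme)
        sub1 = LandcoverGrid(
            np.where(zmask, grid_t1.values, grid_t1.scheme.nodata_code),
            grid_t1.cell_area, grid_t1.scheme)
        tm = compute_transition_matrix(sub0, sub1, start_year, end_year)
        matrices[int(zone)] = tm
        summ = summarize_change(tm, interval_years)
        changed = tm.total_area - float(np.trace(tm.area.values))
        summ = summ.reset_index()
        summ.insert(0, "zone", int(zone))
        summ["zone_percent_gross_change"] = 100.0 * changed / tm.total_area
        rows.append(summ)
    return matrices, pd.concat(rows, ignore_index=True)


def transitions_long(tm: TransitionMatrix) -> pd.DataFrame:
    """Tidy (from_class, to_class, area) export of the nonzero flows."""
    long = tm.area.stack()
    long = long[long > 0].reset_index()
    long.columns = ["from_class", "to_class", "area"]
    return long


def transitions_from_long(
    long: pd.DataFrame, start_year: int = 0, end_year: int = 0
) -> TransitionMatrix:
    """Rebuild a transition matrix from its tidy export (round trip)."""
    ids = sorted(set(long["from_class"]) | set(long["to_class"]))
    area = pd.DataFrame(0.0, index=ids, columns=ids)
    for _, r in long.iterrows():
        area.loc[r["from_class"], r["to_class"]] += r["area"]
    return TransitionMatrix(area, start_year, end_year)
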