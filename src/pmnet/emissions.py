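"""Link measured concentration increments to a gridded emissions inventory.

The inventory reports PM2.5 emitted per day in each 4 x 4 km grid cell,
split into weekday and weekend values.  For each cell holding sensors,
the analysis averages the member sensors over hours (of the given day
type) when *all* of the cell's sensors report, subtracts the lowest cell
mean (the "background" cell, which by construction gets increment 0), and
regresses the increments on the inventory emissions.  A strong fit means
the inventory captures the relative spatial pattern of emissions; cells
with large residuals flag either unrepresentative monitor placement or
processes the inventory misses (e.g. secondary aerosol).

Cells are half-open axis-aligned squares on a local km projection;
boundary points belong to the lower-left cell.  Weekday/weekend follows
the local calendar (Mon-Fri vs Sat-Sun); holidays count as weekdays
unless a holiday list is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import InsufficientDataError, ValidationError

logger = logging.getLogger("pmnet")

DEFAULT_CELL_KM = 4.0


@dataclass(frozen=True)
class EmissionCell:
    cell_id: str
    bounds: tuple[float, float, float, float]  # (min_x, min_y, max_x, max_y), km
    weekday_emissions: float  # tons/day
    weekend_emissions: float  # tons/day
    member_sites: tuple[str, ...] = ()

    def __post_init__(self):
        if self.weekday_emissions < 0 or self.weekend_emissions < 0:
            raise ValidationError("emissions must be nonnegative")
        x0, y0, x1, y1 = self.bounds
        if not (x0 < x1 and y0 < y1):
            raise ValidationError("cell bounds must be a nonempty rectangle")

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bounds
        return (x0 <= x < x1) and (y0 <= y < y1)


def local_xy_km(sites: pd.DataFrame, origin: tuple[float, float] | None = None) -> pd.DataFrame:
    """Project site lat/lon to km east/north of an origin (equirectangular).

    Adequate at city scale; the origin defaults to the south-west corner
    of the site set.
    """
    lat0 = sites["lat"].min() if origin is None else origin[0]
    lon0 = sites["lon"].min() if origin is None else origin[1]
    km_per_deg = 2 * np.pi * 6371.0 / 360.0
    out = sites.copy()
    out["x_km"] = (sites["lon"] - lon0) * km_per_deg * np.cos(np.radians(lat0))
    out["y_km"] = (sites["lat"] - lat0) * km_per_deg
    return out


def assign_sites_to_cells(cells: list[EmissionCell], sites_xy: pd.DataFrame) -> list[EmissionCell]:
    """Re-create cells with ``member_sites`` filled by point-in-cell tests."""
    out = []
    for cell in cells:
        members = tuple(
            str(row.site_id) for row in sites_xy.itertuples() if cell.contains(row.x_km, row.y_km)
        )
        out.append(EmissionCell(cell.cell_id, cell.bounds, cell.weekday_emissions, cell.weekend_emissions, members))
    return out


def _day_type_mask(index: pd.DatetimeIndex, day_type: str, holidays=()) -> np.ndarray:
    is_weekend = index.dayofweek >= 5
    if len(holidays):
        holiday_dates = {pd.Timestamp(h).date() for h in holidays}
        is_weekend = is_weekend | np.array([t.date() in holiday_dates for t in index])
    if day_type == "weekday":
        return ~is_weekend
    if day_type == "weekend":
        return np.asarray(is_weekend)
    raise ValidationError("day_type must be 'weekday' or 'weekend'")


def cell_average(
    series_by_site: dict[str, pd.Series] | pd.DataFrame,
    cells: list[EmissionCell],
    day_type: str = "weekday",
    holidays=(),
) -> pd.DataFrame:
    """Per-cell mean PM2.5 and increment above the background cell.

    For each cell, only hours (of the requested day type) when every
    member sensor reports enter the average; cells with no qualifying
    hours are excluded with a warning.  The increment subtracts the
    minimum cell mean, so exactly one cell has increment 0.
    """
    if isinstance(series_by_site, pd.DataFrame):
        series_by_site = {c: series_by_site[c] for c in series_by_site.columns}
    rows = []
    for cell in cells:
        if not cell.member_sites:
            raise ValidationError(f"cell {cell.cell_id} has no member sites")
        missing = [s for s in cell.member_sites if s not in series_by_site]
        if missing:
            raise ValidationError(f"cell {cell.cell_id}: no series for sites {missing}")
        block = pd.concat({s: series_by_site[s] for s in cell.member_sites}, axis=1)
        block = block[_day_type_mask(block.index, day_type, holidays)].dropna(how="any")
        if block.empty:
            logger.warning("QC: cell %s has no %s hours with all sensors reporting", cell.cell_id, day_type)
            continue
        rows.append(
            {
                "cell_id": cell.cell_id,
                "mean_pm": float(block.to_numpy().mean()),
                "n_hours": int(len(block)),
                "day_type": day_type,
            }
        )
    if not rows:
        raise InsufficientDataError("no cells with qualifying hours")
    table = pd.DataFrame(rows)
    table["increment"] = table["mean_pm"] - table["mean_pm"].min()
    return table.set_index("cell_id")


def regress_increment_vs_ei(increments: pd.DataFrame, cells: list[EmissionCell]) -> dict:
    """OLS of cell increments on inventory emissions for one day type.

    Returns slope/intercept/R2, per-cell residuals, and the cells with
    the largest absolute residuals.
    """
    day_type = increments["day_type"].iloc[0]
    emis = {
        c.cell_id: (c.weekday_emissions if day_type == "weekday" else c.weekend_emissions) for c in cells
    }
    table = increments.copy()
    table["emissions"] = [emis[c] for c in table.index]
    if len(table) < 3:
        raise InsufficientDataError("emissions regression needs at least 3 cells")
    res = stats.linregress(table["emissions"], table["increment"])
    predicted = res.intercept + res.slope * table["emissions"]
    residuals = table["increment"] - predicted
    order = residuals.abs().sort_values(ascending=False)
    return {
        "day_type": day_type,
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n_cells": int(len(table)),
        "residuals": residuals,
        "largest_residual_cells": list(order.index[:2]),
    }


def read_ei_csv(path) -> list[EmissionCell]:
    """Read cells from ``cell_id,min_x,min_y,max_x,max_y,weekday_tons_per_day,weekend_tons_per_day``."""
    df = pd.read_csv(path)
    needed = {"cell_id", "min_x", "min_y", "max_x", "max_y", "weekday_tons_per_day", "weekend_tons_per_day"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"EI CSV missing columns: {sorted(missing)}")
    return [
        EmissionCell(
            str(r.cell_id),
            (float(r.min_x), float(r.min_y), float(r.max_x), float(r.max_y)),
            float(r.weekday_tons_per_day),
            float(r.weekend_tons_per_day),
        )
        for r in df.itertuples()
    ]


def write_ei_csv(cells: list[EmissionCell], path) -> None:
    pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "min_x": c.bounds[0],
                "min_y": c.bounds[1],
                "max_x": c.bounds[2],
                "max_y": c.bounds[3],
                "weekday_tons_per_day": c.weekday_emissions,
                "weekend_tons_per_day": c.weekend_emissions,
            }
            for c in cells
        ]
    ).to_csv(path, index=False)
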