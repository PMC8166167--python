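"""Checklist filtering, gridding, and relative-abundance computation.

Relative abundance (RA) of a species in a grid cell is the mean number of
individuals recorded per complete checklist, zeros included, computed
month-first: a monthly mean over all the cell's checklists in that month,
then an unweighted mean over months that have at least one checklist.
RA is an effort-standardised index, not a density; the training regression
links the two on the log10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import c4_factor, delta_method_se_log10

EVENT_FIELDS = ["checklist_id", "lat", "lon", "month", "duration_min",
                "distance_km", "complete"]

#: Mean length of one degree of latitude, km.
KM_PER_DEG = 111.2


@dataclass
class ChecklistTable:
    """Checklist events plus the positive per-species counts they recorded.

    ``events`` has one row per sampling event (:data:`EVENT_FIELDS`, plus
    ``grid_id`` once assigned); ``counts`` has one row per (checklist,
    species) with a positive count.  Species absent from a complete
    checklist are implicitly zero.
    """

    events: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [f for f in EVENT_FIELDS if f not in self.events.columns]
        if missing:
            raise ValueError(f"checklist events missing fields: {missing}")
        if self.events["checklist_id"].duplicated().any():
            raise ValueError("duplicate checklist ids")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_long(self) -> pd.DataFrame:
        """Long-format join (one row per positive species count)."""
        return self.counts.merge(self.events, on="checklist_id", how="left")

    def write_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ChecklistTable":
        long = pd.read_csv(path)
        extra = [c for c in ("grid_id",) if c in long.columns]
        events = long[EVENT_FIELDS + extra].drop_duplicates("checklist_id")
        counts = long[["checklist_id", "species_id", "count"]]
        return cls(events.reset_index(drop=True), counts.reset_index(drop=True))


@dataclass
class GridSpec:
    """A half-open latitude/longitude lattice of square cells.

    Cells are ``cell_deg`` degrees on a side, anchored at the bottom-left
    corner ``(lat0, lon0)``, identified by row-major integers.  Boundaries
    are half-open ``[lo, hi)`` in both axes, so a point exactly on a
    boundary belongs to the higher cell.
    """

    n_rows: int
    n_cols: int
    cell_deg: float = 5.0
    lat0: float = -60.0
    lon0: float = -180.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_deg <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def assign(self, lat, lon) -> np.ndarray:
        """Row-major cell id per point; -1 for points outside the domain."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        row = np.floor((lat - self.lat0) / self.cell_deg).astype(int)
        col = np.floor((lon - self.lon0) / self.cell_deg).astype(int)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        return np.where(ok, row * self.n_cols + col, -1)

    def cell_center(self, grid_id) -> tuple[np.ndarray, np.ndarray]:
        grid_id = np.asarray(grid_id)
        row, col = divmod(grid_id, self.n_cols)
        lat = self.lat0 + (row + 0.5) * self.cell_deg
        lon = self.lon0 + (col + 0.5) * self.cell_deg
        return lat, lon

    def cell_area_km2(self, grid_id) -> np.ndarray:
        """Spherical-rectangle area, cos(latitude)-scaled."""
        lat, _ = self.cell_center(np.asarray(grid_id))
        side = self.cell_deg * KM_PER_DEG
        return side * side * np.cos(np.deg2rad(lat))


def filter_checklists(table: ChecklistTable) -> ChecklistTable:
    """Keep best-quality checklists: complete, >5 and <240 min, <5 km.

    All comparisons are strict; row order is preserved.  Counts belonging
    to dropped checklists are dropped with them.
    """
    ev = table.events
    for f in ("complete", "duration_min", "distance_km"):
        if ev[f].isna().any():
            raise ValueError(f"effort field '{f}' contains missing values")
    keep = (
        ev["complete"].astype(bool)
        & (ev["duration_min"] > 5)
        & (ev["duration_min"] < 240)
        & (ev["distance_km"] < 5)
    )
    events = ev.loc[keep].reset_index(drop=True)
    kept_ids = set(events["checklist_id"])
    counts = table.counts[table.counts["checklist_id"].isin(kept_ids)]
    return ChecklistTable(events, counts.reset_index(drop=True))


def assign_and_select_grids(
    table: ChecklistTable,
    grid: GridSpec,
    min_checklists: int = 50,
) -> tuple[ChecklistTable, set[int], int]:
    """Assign checklists to grid cells and find the eligible cells.

    A cell is eligible iff it holds at least ``min_checklists`` checklists
    within at least one calendar month.  Checklists outside the grid domain
    are excluded; their number is returned as the third element.
    """
    ev = table.events.copy()
    gid = grid.assign(ev["lat"].to_numpy(), ev["lon"].to_numpy())
    n_outside = int((gid < 0).sum())
    ev["grid_id"] = gid
    ev = ev[ev["grid_id"] >= 0].reset_index(drop=True)
    counts = table.counts[table.counts["checklist_id"].isin(set(ev["checklist_id"]))]
    per_month = ev.groupby(["grid_id", "month"]).size()
    if len(per_month):
        max_month = per_month.groupby("grid_id").max()
        eligible = set(max_month.index[max_month >= min_checklists])
    else:
        eligible = set()
    return ChecklistTable(ev, counts.reset_index(drop=True)), eligible, n_outside


def relative_abundance_table(
    table: ChecklistTable,
    eligible: set[int] | None = None,
) -> pd.DataFrame:
    """Per-(species, grid) relative abundance over eligible cells.

    Returns one row per species × grid combination in which the species was
    recorded at least once, with columns ``species_id, grid_id, rel_abund,
    n_checklists, log_n_checklists, n_months_observed, reporting_rate``.
    Cells without a single checklist contribute nothing.
    """
    ev = table.events
    if "grid_id" not in ev.columns:
        raise ValueError("run assign_and_select_grids first (no grid_id column)")
    if eligible is not None:
        ev = ev[ev["grid_id"].isin(eligible)]
    if ev.empty:
        return pd.DataFrame(columns=[
            "species_id", "grid_id", "rel_abund", "n_checklists",
            "log_n_checklists", "n_months_observed", "reporting_rate"])

    # checklists per (grid, month) — the monthly-mean denominators
    eff = ev.groupby(["grid_id", "month"]).size().rename("n_cl").reset_index()
    n_months_grid = eff.groupby("grid_id").size().rename("n_months")
    n_cl_grid = ev.groupby("grid_id").size().rename("n_checklists")

    long = table.counts.merge(
        ev[["checklist_id", "grid_id", "month"]], on="checklist_id", how="inner")
    if long.empty:
        return pd.DataFrame(columns=[
            "species_id", "grid_id", "rel_abund", "n_checklists",
            "log_n_checklists", "n_months_observed", "reporting_rate"])

    by_sm = (long.groupby(["species_id", "grid_id", "month"])
             .agg(total=("count", "sum"), n_lists=("checklist_id", "nunique"))
             .reset_index())
    by_sm = by_sm.merge(eff, on=["grid_id", "month"])
    by_sm["monthly_mean"] = by_sm["total"] / by_sm["n_cl"]

    out = (by_sm.groupby(["species_id", "grid_id"])
           .agg(sum_monthly=("monthly_mean", "sum"),
                n_months_observed=("month", "nunique"),
                n_lists_with=("n_lists", "sum"))
           .reset_index())
    out = out.merge(n_months_grid, on="grid_id").merge(n_cl_grid, on="grid_id")
    # months without a record of the species contribute a zero monthly mean
    out["rel_abund"] = out["sum_monthly"] / out["n_months"]
    out["reporting_rate"] = out["n_lists_with"] / out["n_checklists"]
    out["log_n_checklists"] = np.log(out["n_checklists"].astype(float))
    return out[["species_id", "grid_id", "rel_abund", "n_checklists",
                "log_n_checklists", "n_months_observed", "reporting_rate"]]


def compute_relative_abundance(
    table: ChecklistTable, species_id, grid_id
) -> dict:
    """RA record for one species in one grid cell (zeros included).

    The monthly mean counts every checklist in the cell that month; the
    cell-level RA is the unweighted mean of the monthly means over months
    with at least one checklist.
    """
    ev = table.events
    ev_g = ev[ev["grid_id"] == grid_id]
    if ev_g.empty:
        raise ValueError(f"grid {grid_id} has no checklists")
    eff = ev_g.groupby("month").size()
    long = table.counts[(table.counts["species_id"] == species_id)
                        & table.counts["checklist_id"].isin(set(ev_g["checklist_id"]))]
    long = long.merge(ev_g[["checklist_id", "month"]], on="checklist_id")
    monthly = long.groupby("month")["count"].sum().reindex(eff.index, fill_value=0)
    monthly_means = monthly / eff
    rel = float(monthly_means.mean())
    return {
        "species_id": species_id,
        "grid_id": grid_id,
        "rel_abund": rel,
        "n_checklists": int(len(ev_g)),
        "n_months_observed": int((monthly > 0).sum()),
        "reporting_rate": float(long["checklist_id"].nunique() / len(ev_g)),
        "monthly_means": monthly_means.to_numpy(dtype=float),
    }


def rel_abund_se(
    strata_means,
    n_checklists: int | None = None,
    small_sample_correction: bool = True,
) -> float:
    """SE of log10 relative abundance from space × time stratum means.

    The linear-scale SE is the SD of the stratum mean estimates (n−1
    denominator), divided by the normality unbiasing constant c4(n) when
    ``small_sample_correction`` is on; the delta method converts it to the
    log10 scale: se_log10 = SE / (mean · ln 10).

    With a single stratum the SD is undefined and a Poisson-based fallback
    is used instead: SE = sqrt(mean / n_checklists).
    """
    means = np.asarray(strata_means, dtype=float)
    if means.size < 1:
        raise ValueError("need at least one stratum mean")
    mean = float(means.mean())
    if mean <= 0:
        return float("nan")
    if means.size == 1:
        if n_checklists is None or n_checklists < 1:
            raise ValueError("single-stratum SE fallback needs n_checklists")
        se_linear = float(np.sqrt(mean / n_checklists))
    else:
        se_linear = float(means.std(ddof=1))
        if small_sample_correction:
            se_linear /= c4_factor(means.size)
    return delta_method_se_log10(mean, se_linear)
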