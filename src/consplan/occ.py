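"""Occurrence-record cleaning: proximity filters, clipping, thinning, rarity filter.

Records are pandas DataFrames with columns ``species, x, y, source``
(planar km coordinates).  The canonical pipeline order is fixed:

1. proximity cleaning — drop records within a buffer of cities (10 km) or
   institutions/museums (100 m), where georeferencing artefacts concentrate;
2. clipping to the study boundary mask;
3. spatial thinning to one record per species per grid cell;
4. rarity filter — drop species left with fewer than five records.

Removal at a buffer is strict (``distance < buffer``): a record exactly on
the buffer edge is retained.  Every step returns the filtered table plus a
:class:`CleaningReport` whose counts are conserved
(``input = retained + sum(removed)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import GridSpec
from .synth import SettlementSet

__all__ = [
    "CleaningReport",
    "remove_near_points",
    "clip_to_boundary",
    "thin_one_per_cell",
    "drop_rare_species",
    "clean_pipeline",
]

REQUIRED_COLUMNS = ("species", "x", "y")


@dataclass
class CleaningReport:
    """Per-rule removal counts and the final per-species tallies."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    retained_per_species: dict[str, int] = field(default_factory=dict)
    dropped_species: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed.values())

    def check_conserved(self) -> bool:
        return self.n_input == self.n_retained + sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": rule, "removed": n} for rule, n in self.removed.items()]
        rows.append({"rule": "(retained)", "removed": self.n_retained})
        return pd.DataFrame(rows)


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if len(records) and not np.isfinite(records[["x", "y"]].to_numpy()).all():
        raise ValueError("occurrence coordinates must be finite")
    return records


def remove_near_points(
    records: pd.DataFrame,
    settlements: SettlementSet,
    city_buffer_km: float = 10.0,
    inst_buffer_km: float = 0.1,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop records strictly within the buffer of a city (10 km) or an
    institution/museum (100 m)."""
    if city_buffer_km < 0 or inst_buffer_km < 0:
        raise ValueError("buffers must be non-negative")
    _validate(records)
    report = CleaningReport(n_input=len(records))
    keep = np.ones(len(records), dtype=bool)
    xy = records[["x", "y"]].to_numpy(dtype=float)
    for kinds, buffer_km, rule in (
        (("city",), city_buffer_km, "near_city"),
        (("institution", "museum"), inst_buffer_km, "near_institution_museum"),
    ):
        pts = settlements.of_kind(*kinds)
        if len(pts) == 0 or len(records) == 0 or buffer_km == 0:
            report.removed[rule] = 0
            continue
        dist, _ = cKDTree(pts).query(xy)
        hit = keep & (dist < buffer_km)
        report.removed[rule] = int(hit.sum())
        keep &= ~hit
    out = records.loc[keep].reset_index(drop=True)
    report.retained_per_species = out.groupby("species").size().to_dict()
    return out, report


def clip_to_boundary(
    records: pd.DataFrame,
    mask: np.ndarray,
    grid: GridSpec,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop records whose cell lies outside the boundary mask (True = inside).

    Records outside the grid bounding box are also dropped.
    """
    _validate(records)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    report = CleaningReport(n_input=len(records))
    if len(records) == 0:
        report.removed["outside_boundary"] = 0
        return records.reset_index(drop=True), report
    x = records["x"].to_numpy(dtype=float)
    y = records["y"].to_numpy(dtype=float)
    in_box = grid.contains(x, y)
    row, col = grid.cell_of(x, y)
    inside = in_box & mask[row, col]
    report.removed["outside_boundary"] = int((~inside).sum())
    out = records.loc[inside].reset_index(drop=True)
    report.retained_per_species = out.groupby("species").size().to_dict()
    return out, report


def thin_one_per_cell(
    records: pd.DataFrame,
    grid: GridSpec,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Keep at most one record per species per grid cell (first in input order)."""
    _validate(records)
    report = CleaningReport(n_input=len(records))
    if len(records) == 0:
        report.removed["duplicate_in_cell"] = 0
        return records.reset_index(drop=True), report
    row, col = grid.cell_of(
        records["x"].to_numpy(dtype=float), records["y"].to_numpy(dtype=float)
    )
    key = pd.DataFrame(
        {"species": records["species"].to_numpy(), "row": row, "col": col}
    )
    first = ~key.duplicated()
    report.removed["duplicate_in_cell"] = int((~first).sum())
    out = records.loc[first.to_numpy()].reset_index(drop=True)
    report.retained_per_species = out.groupby("species").size().to_dict()
    return out, report


def drop_rare_species(
    records: pd.DataFrame,
    min_records: int = 5,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove species with fewer than ``min_records`` records (default 5)."""
    if min_records < 1:
        raise ValueError("min_records must be >= 1")
    _validate(records)
    report = CleaningReport(n_input=len(records))
    if len(records) == 0:
        report.removed["rare_species"] = 0
        return records.reset_index(drop=True), report
    counts = records.groupby("species").size()
    rare = counts[counts < min_records].index
    hit = records["species"].isin(rare)
    report.removed["rare_species"] = int(hit.sum())
    report.dropped_species = sorted(rare)
    out = records.loc[~hit].reset_index(drop=True)
    report.retained_per_species = out.groupby("species").size().to_dict()
    return out, report


def clean_pipeline(
    records: pd.DataFrame,
    settlements: SettlementSet | None,
    grid: GridSpec,
    boundary_mask: np.ndarray | None = None,
    city_buffer_km: float = 10.0,
    inst_buffer_km: float = 0.1,
    min_records: int = 5,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full cleaning chain in the canonical order and merge reports."""
    report = CleaningReport(n_input=len(records))
    out = records
    if settlements is not None:
        out, r = remove_near_points(out, settlements, city_buffer_km, inst_buffer_km)
        report.removed.update(r.removed)
    if boundary_mask is not None:
        out, r = clip_to_boundary(out, boundary_mask, grid)
        report.removed.update(r.removed)
    out, r = thin_one_per_cell(out, grid)
    report.removed.update(r.removed)
    out, r = drop_rare_species(out, min_records)
    report.removed.update(r.removed)
    report.dropped_species = r.dropped_species
    report.retained_per_species = (
        out.groupby("species").size().to_dict() if len(out) else {}
    )
    return out, report
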