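"""Species richness, rarity-weighted richness, and map/statistic comparisons.

Richness is the per-cell count of occupying species.  Rarity-weighted
richness (RWR) weighs each resident species by the inverse of its
occupied-cell count ``c_i``::

    RWR(cell) = sum over the n species present in the cell of 1 / c_i

so a single-cell endemic contributes its maximum score 1.0 where it lives,
a 100-cell species contributes 0.01 per cell, and every extant species
contributes exactly 1 in total across the map — the conservation property
the tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .grids import BinaryRange, GridSpec

__all__ = [
    "RichnessMap",
    "RWRMap",
    "richness",
    "richness_change",
    "rarity_score",
    "rwr",
    "pearson_map_correlation",
    "wilcoxon_paired",
    "wilcoxon_twosample",
    "range_loss_fraction",
    "pa_range_loss_test",
]


@dataclass
class RichnessMap:
    grid: GridSpec
    values: np.ndarray  # integer counts
    scenario: str


@dataclass
class RWRMap:
    grid: GridSpec
    values: np.ndarray  # nonnegative reals
    scenario: str


def _check_shared(ranges: list[BinaryRange]) -> tuple[GridSpec, str]:
    if not ranges:
        raise ValueError("empty range list")
    grid = ranges[0].grid
    scenario = ranges[0].scenario
    for r in ranges:
        if r.grid != grid:
            raise ValueError("ranges must share one grid")
        if r.scenario != scenario:
            raise ValueError(
                f"mixed scenarios in one call: {r.scenario!r} vs {scenario!r}"
            )
    return grid, scenario


def richness(ranges: list[BinaryRange]) -> RichnessMap:
    """Per-cell count of occupying species."""
    if not ranges:
        raise ValueError("empty range list")
    grid, scenario = _check_shared(ranges)
    values = np.zeros(grid.shape, dtype=int)
    for r in ranges:
        values += r.mask
    return RichnessMap(grid, values, scenario)


def richness_change(current: RichnessMap, future: RichnessMap) -> np.ndarray:
    """Signed per-cell change, future minus current."""
    if current.grid != future.grid:
        raise ValueError("grid mismatch")
    return future.values - current.values


def rarity_score(c: int) -> float:
    """Rarity score 1/c for a species occupying ``c`` cells (c >= 1)."""
    if c < 1:
        raise ValueError(
            "rarity score undefined for c = 0 (species is locally extinct)"
        )
    return 1.0 / c


def rwr(ranges: list[BinaryRange]) -> RWRMap:
    """Rarity-weighted richness map; species with c = 0 contribute nothing.

    Locally extinct species (empty ranges) are silently skipped here; callers
    wanting the extinction list should filter on ``r.is_empty`` first.
    """
    grid, scenario = _check_shared(ranges)
    values = np.zeros(grid.shape, dtype=float)
    for r in ranges:
        if r.is_empty:
            continue
        values += r.mask / r.c
    return RWRMap(grid, values, scenario)


def pearson_map_correlation(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Product-moment correlation of two maps over the (optional) mask."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if len(a) < 3:
        raise ValueError("need at least 3 paired values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: one map has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def wilcoxon_paired(values_a, values_b) -> tuple[float, float]:
    """Wilcoxon signed-rank test (normal approximation with tie correction).

    Returns (Z, two-sided p).  Zero differences are dropped per the classic
    procedure; an all-zero difference vector is signalled as an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must share a shape")
    d = a - b
    d = d[d != 0]
    if len(d) < 3:
        raise ValueError(
            "signed-rank test undefined: fewer than 3 nonzero differences"
        )
    # signed Z from W+ under sign-flip randomization; average ranks make
    # Var = sum(r^2)/4 carry the tie correction automatically
    r = scipy.stats.rankdata(np.abs(d))
    w_plus = r[d > 0].sum()
    z = (w_plus - r.sum() / 2) / np.sqrt((r**2).sum() / 4)
    p = 2 * scipy.stats.norm.sf(abs(z))
    return float(z), float(p)


def wilcoxon_twosample(values_a, values_b) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) alternative; returns (Z, two-sided p)."""
    res = scipy.stats.ranksums(values_a, values_b)
    return float(res.statistic), float(res.pvalue)


def range_loss_fraction(
    current: BinaryRange, future: BinaryRange, region_mask: np.ndarray | None = None
) -> float:
    """Proportional range loss (c_now - c_future) / c_now within a region.

    NaN when the species occupies no cell of the region now.
    """
    cur = current.mask
    fut = future.mask
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        cur = cur & region_mask
        fut = fut & region_mask
    c_now = int(cur.sum())
    if c_now == 0:
        return np.nan
    return (c_now - int(fut.sum())) / c_now


def pa_range_loss_test(
    current_ranges: list[BinaryRange],
    future_ranges: list[BinaryRange],
    pa_mask: np.ndarray,
) -> tuple[float, float, pd.DataFrame]:
    """Paired signed-rank test of per-species range loss inside vs outside PAs.

    Species with no current range in a region are excluded.  Returns
    (Z, p, per-species loss table).
    """
    pa_mask = np.asarray(pa_mask, dtype=bool)
    rows = []
    future_by_id = {r.species_id: r for r in future_ranges}
    for cur in current_ranges:
        fut = future_by_id.get(cur.species_id)
        if fut is None:
            continue
        rows.append(
            {
                "species": cur.species_id,
                "loss_inside": range_loss_fraction(cur, fut, pa_mask),
                "loss_outside": range_loss_fraction(cur, fut, ~pa_mask),
            }
        )
    table = pd.DataFrame(rows)
    paired = table.dropna()
    z, p = wilcoxon_paired(
        paired["loss_inside"].to_numpy(), paired["loss_outside"].to_numpy()
    )
    return z, p, table
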