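"""Protected-area gap analysis: range representation inside the PA network.

Each species' binary range is intersected with the PA mask; the percentage
inside is binned into five representation categories with upper-inclusive
boundaries:

=======================  ==================
category                 pct of range in PA
=======================  ==================
Unprotected              0 – 10 (incl.)
Inadequately protected   > 10 – 30 (incl.)
Partially protected      > 30 – 50 (incl.)
Adequately protected     > 50 – 80 (incl.)
Protected                > 80 – 100
=======================  ==================

The bins partition [0, 100]; species whose range is entirely outside the
network are additionally flagged ``fully_outside``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import BinaryRange

__all__ = [
    "CATEGORIES",
    "ProtectionRecord",
    "pct_inside",
    "classify",
    "protection_record",
    "summarize",
    "count_fully_outside",
]

# (upper bound, name); upper-inclusive bins over [0, 100]
_BINS = (
    (10.0, "Unprotected"),
    (30.0, "Inadequately protected"),
    (50.0, "Partially protected"),
    (80.0, "Adequately protected"),
    (100.0, "Protected"),
)
CATEGORIES = tuple(name for _, name in _BINS)


@dataclass
class ProtectionRecord:
    species_id: str
    scenario: str
    range_area_km2: float
    inside_area_km2: float
    pct_inside: float
    category: str
    fully_outside: bool
    taxon: str = ""


def pct_inside(species_range: BinaryRange, pa_mask: np.ndarray) -> float:
    """Percentage of the occupied cells lying inside the PA mask."""
    pa_mask = np.asarray(pa_mask, dtype=bool)
    if pa_mask.shape != species_range.grid.shape:
        raise ValueError("PA mask shape does not match the range grid")
    c = species_range.c
    if c == 0:
        raise ValueError(
            f"{species_range.species_id!r}: empty range — protection undefined; "
            "report the species as locally extinct instead"
        )
    inside = int((species_range.mask & pa_mask).sum())
    return 100.0 * inside / c


def classify(pct: float) -> str:
    """Map a protection percentage to its representation category."""
    if not 0 <= pct <= 100:
        raise ValueError(f"pct must be in [0, 100], got {pct}")
    for upper, name in _BINS:
        if pct <= upper:
            return name
    raise AssertionError("unreachable")  # bins cover [0, 100]


def protection_record(
    species_range: BinaryRange, pa_mask: np.ndarray, taxon: str = ""
) -> ProtectionRecord:
    """Full gap-analysis record for one species under one scenario."""
    pct = pct_inside(species_range, pa_mask)
    area = species_range.area_km2
    inside_area = area * pct / 100.0
    return ProtectionRecord(
        species_id=species_range.species_id,
        scenario=species_range.scenario,
        range_area_km2=area,
        inside_area_km2=inside_area,
        pct_inside=pct,
        category=classify(pct),
        fully_outside=pct == 0.0,
        taxon=taxon,
    )


def _records_frame(records: list[ProtectionRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def summarize(records: list[ProtectionRecord]) -> pd.DataFrame:
    """Category percentages per (taxon, scenario); rows sum to 100."""
    if not records:
        raise ValueError("no protection records to summarize")
    df = _records_frame(records)
    df["category"] = pd.Categorical(df["category"], categories=CATEGORIES)
    out = (
        df.groupby(["taxon", "scenario"], observed=False)["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        * 100.0
    )
    return out.reset_index()


def count_fully_outside(records: list[ProtectionRecord]) -> int:
    """Number of species whose range falls entirely outside the PA network."""
    return sum(r.fully_outside for r in records)
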