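"""Interannual habitat-suitability change maps and suitable-area accounting.

Change maps difference the continuous HSI surfaces of two years; the area
table counts suitable cells in the binary maps, converts them to km², and
reports first differences and the percentage of a configured total area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Grid

__all__ = [
    "ChangeMap",
    "AreaSummary",
    "hsi_change",
    "suitable_area_km2",
    "area_summary",
    "AKAGERA_TOTAL_KM2",
    "AKAGERA_SUITABLE_KM2",
]

#: Akagera National Park (Rwanda) total area, km².
AKAGERA_TOTAL_KM2 = 1122.0

#: Published annual suitable-habitat area (km²) for Lantana camara in
#: Akagera NP, 2015-2023, from the habitat-suitability study this package
#: operationalises. Useful as reference input for the area accounting.
AKAGERA_SUITABLE_KM2: dict[int, float] = {
    2015: 230.01,
    2016: 295.18,
    2017: 206.05,
    2018: 196.05,
    2019: 163.79,
    2020: 210.19,
    2021: 281.87,
    2022: 225.90,
    2023: 364.85,
}


@dataclass
class ChangeMap:
    """Per-cell HSI difference between two years (year_b − year_a)."""

    delta: Grid
    year_a: int
    year_b: int


@dataclass
class AreaSummary:
    """Annual suitable area, first differences, and share of total area."""

    table: pd.DataFrame  # columns: year, suitable_km2, annual_change_km2, percent_of_total
    total_km2: float

    @property
    def max_percent_year(self) -> int:
        idx = self.table["percent_of_total"].idxmax()
        return int(self.table.loc[idx, "year"])

    @property
    def max_percent(self) -> float:
        return float(self.table["percent_of_total"].max())

    def rounded_max_percent(self) -> int:
        """Headline figure: the maximum annual share, nearest whole percent."""
        return int(round(self.max_percent))


def hsi_change(hsi_a: Grid, hsi_b: Grid, year_a: int = 0, year_b: int = 0) -> ChangeMap:
    """Pixel change map HSI_b − HSI_a; masks are unioned."""
    if hsi_a.geometry != hsi_b.geometry:
        raise ValueError("HSI grids do not share a geometry")
    mask = hsi_a.nodata_mask | hsi_b.nodata_mask
    delta = np.where(mask, 0.0, hsi_b.values - hsi_a.values)
    return ChangeMap(Grid(delta, hsi_a.geometry, mask), year_a, year_b)


def suitable_area_km2(binary: Grid) -> float:
    """Area of unmasked suitable (value 1) cells in km²."""
    vals = binary.masked_values()
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("grid is not binary")
    cell_km = binary.geometry.cell_size_m / 1000.0
    return float(vals.sum() * cell_km * cell_km)


def area_summary(binary_by_year: dict[int, "Grid | float"], total_km2: float) -> AreaSummary:
    """Annual suitable-area table with first differences and percentages.

    Values may be binary Grids (areas are counted) or precomputed km²
    figures. ``annual_change_km2`` is suitable[y] − suitable[y−1] in year
    order (NaN for the first year); ``percent_of_total`` is
    100·suitable/total.
    """
    if total_km2 is None or total_km2 <= 0:
        raise ValueError("a positive total_km2 is required")
    years = sorted(binary_by_year)
    areas = [
        suitable_area_km2(v) if isinstance(v, Grid) else float(v)
        for v in (binary_by_year[y] for y in years)
    ]
    changes = [np.nan] + [areas[i] - areas[i - 1] for i in range(1, len(areas))]
    table = pd.DataFrame(
        {
            "year": years,
            "suitable_km2": areas,
            "annual_change_km2": changes,
            "percent_of_total": [100.0 * a / total_km2 for a in areas],
        }
    )
    return AreaSummary(table, float(total_km2))
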