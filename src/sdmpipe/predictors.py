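"""Predictor-band construction: roads, radar backscatter, vegetation indices,
land cover, and stack assembly.

The canonical habitat-model configuration uses 52 gridded predictors
(`PREDICTOR_NAMES`): a buffered road raster, five terrain bands, six
climate bands, fourteen soil bands (top- and subsoil), six one-hot land
cover classes, two SAR backscatter polarisations in dB, ten multispectral
reflectance bands, and eight vegetation indices derived from them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, MultiLineString

from .grids import Grid, GridGeometry, PredictorStack

__all__ = [
    "RoadNetwork",
    "IndexSpec",
    "PREDICTOR_NAMES",
    "VEGETATION_INDICES",
    "load_roads",
    "buffer_rasterize_roads",
    "to_decibel",
    "compute_index",
    "onehot_landcover",
    "assemble_stack",
]

#: The 52 predictor bands of the full habitat model, grouped by category.
PREDICTOR_NAMES: tuple[str, ...] = (
    # anthropogenic
    "Roads",
    # topography
    "Aspect", "Elevation", "Slope", "TPI", "TWI",
    # climate (11-month medians)
    "AET", "PET", "TMMX", "TMMN", "P", "SOIL",
    # soil, topsoil (_TS) and subsoil (_SS)
    "Sand_TS", "Sand_SS", "Clay_TS", "Clay_SS", "C_TS", "C_SS",
    "ECC_TS", "ECC_SS", "N_TS", "N_SS", "P_TS", "P_SS", "pH_TS", "pH_SS",
    # land cover (one-hot, water excluded via the water mask)
    "Bare_Ground", "Bushland", "Forest", "Grassland", "Wetland", "Woodland",
    # SAR backscatter (dB)
    "VH", "VV",
    # multispectral reflectance
    "Blue", "Green", "Red", "RE1", "RE2", "RE3", "NIR", "RE4", "SWIR1", "SWIR2",
    # vegetation indices
    "CCCI", "GNDVI", "NDRE", "NDVI", "RVI", "SAVI_L05", "SAVI_L1", "TVI",
)

VEGETATION_INDICES = ("CCCI", "GNDVI", "NDRE", "NDVI", "RVI", "SAVI", "TVI")


@dataclass
class RoadNetwork:
    """Road polylines in map coordinates (metres)."""

    polylines: list[list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for line in self.polylines:
            if len(line) < 2:
                raise ValueError("each polyline needs at least two vertices")

    def to_shapely(self) -> MultiLineString:
        return MultiLineString([LineString(line) for line in self.polylines])

    @property
    def is_empty(self) -> bool:
        return not self.polylines


def load_roads(path) -> RoadNetwork:
    """Load roads from a GeoJSON file of LineString/MultiLineString features."""
    path = Path(path)
    obj = json.loads(path.read_text())
    geoms = []
    if obj.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in obj.get("features", [])]
    elif obj.get("type") == "Feature":
        geoms = [obj["geometry"]]
    else:
        geoms = [obj]
    polylines: list[list[tuple[float, float]]] = []
    for g in geoms:
        if g is None:
            continue
        gtype = g.get("type")
        if gtype == "LineString":
            polylines.append([tuple(c[:2]) for c in g["coordinates"]])
        elif gtype == "MultiLineString":
            polylines.extend([tuple(c[:2]) for c in part] for part in g["coordinates"])
        else:
            raise ValueError(f"unsupported road geometry type: {gtype}")
    return RoadNetwork(polylines)


def save_roads(roads: RoadNetwork, path) -> Path:
    path = Path(path)
    geo = {
        "type": "Feature",
        "properties": {},
        "geometry": {
            "type": "MultiLineString",
            "coordinates": [[list(pt) for pt in line] for line in roads.polylines],
        },
    }
    path.write_text(json.dumps(geo))
    return path


def buffer_rasterize_roads(
    roads: RoadNetwork, buffer_m: float, geometry: GridGeometry
) -> Grid:
    """Binary road raster: 1 where the cell center is within ``buffer_m``
    (Euclidean) of any road segment, else 0.

    Membership is decided at cell centers, consistent with the point-to-cell
    convention used everywhere else.
    """
    if buffer_m <= 0:
        raise ValueError("buffer_m must be positive")
    if roads.is_empty:
        warnings.warn("empty road network: road raster is all zero", stacklevel=2)
        return Grid(np.zeros(geometry.shape), geometry)
    xs, ys = geometry.center_coords()
    pts = shapely.points(xs.ravel(), ys.ravel())
    dist = shapely.distance(roads.to_shapely(), pts).reshape(geometry.shape)
    return Grid((dist <= buffer_m).astype(np.float64), geometry)


def to_decibel(linear: Grid) -> Grid:
    """Convert backscatter from linear power units to decibels, 10·log10(x).

    Non-positive unmasked values cannot be represented in dB; those cells
    are masked with a warning.
    """
    bad = linear.valid & (linear.values <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-positive backscatter cells masked in dB conversion",
            stacklevel=2,
        )
    mask = linear.nodata_mask | bad
    out = np.zeros_like(linear.values)
    ok = ~mask
    out[ok] = 10.0 * np.log10(linear.values[ok])
    return Grid(out, linear.geometry, mask)


@dataclass
class IndexSpec:
    """A vegetation index and its parameters.

    ``L`` is the SAVI soil-adjustment factor (the model uses both 0.5 and
    1.0); ``red_edge`` names the red-edge band used by NDRE and CCCI;
    ``tvi_form`` selects the square-root TVI (default, the standard form)
    or the plain additive variant NDVI + 0.5.
    """

    name: str
    L: float = 0.5
    red_edge: str = "RE1"
    tvi_form: str = "sqrt"

    def __post_init__(self) -> None:
        if self.name not in VEGETATION_INDICES:
            raise ValueError(f"unknown index {self.name!r}; known: {VEGETATION_INDICES}")
        if self.name == "SAVI" and self.L <= 0:
            raise ValueError("SAVI requires L > 0")
        if self.tvi_form not in ("sqrt", "additive"):
            raise ValueError("tvi_form must be 'sqrt' or 'additive'")


def _band(stack: PredictorStack, name: str) -> np.ndarray:
    if name not in stack:
        raise KeyError(f"band {name!r} missing from stack")
    return stack[name].values


def _ratio(num: np.ndarray, den: np.ndarray, base_mask: np.ndarray):
    """Safe division; zero denominators are masked, never clipped."""
    zero = np.isclose(den, 0.0)
    out = np.zeros_like(num)
    ok = ~zero
    out[ok] = num[ok] / den[ok]
    return out, base_mask | zero


def compute_index(spec: IndexSpec, stack: PredictorStack) -> Grid:
    """Compute a vegetation index from the stack's reflectance bands.

    Normalised-difference indices (NDVI, GNDVI, NDRE) lie in [-1, 1] for
    non-negative reflectances. Cells with a zero denominator — and, for the
    square-root TVI, a negative radicand — are masked.
    """
    geom = stack.geometry
    mask0 = stack.combined_mask()
    name = spec.name
    if name == "NDVI":
        nir, red = _band(stack, "NIR"), _band(stack, "Red")
        vals, mask = _ratio(nir - red, nir + red, mask0)
    elif name == "GNDVI":
        nir, green = _band(stack, "NIR"), _band(stack, "Green")
        vals, mask = _ratio(nir - green, nir + green, mask0)
    elif name == "NDRE":
        nir, re = _band(stack, "NIR"), _band(stack, spec.red_edge)
        vals, mask = _ratio(nir - re, nir + re, mask0)
    elif name == "RVI":
        nir, red = _band(stack, "NIR"), _band(stack, "Red")
        vals, mask = _ratio(nir, red, mask0)
    elif name == "SAVI":
        nir, red = _band(stack, "NIR"), _band(stack, "Red")
        vals, mask = _ratio(nir - red, nir + red + spec.L, mask0)
        vals = vals * (1.0 + spec.L)
    elif name == "CCCI":
        # ratio of the red-edge normalised difference to NDVI
        ndre = compute_index(IndexSpec("NDRE", red_edge=spec.red_edge), stack)
        ndvi = compute_index(IndexSpec("NDVI"), stack)
        vals, mask = _ratio(ndre.values, ndvi.values, ndre.nodata_mask | ndvi.nodata_mask)
    elif name == "TVI":
        ndvi = compute_index(IndexSpec("NDVI"), stack)
        shifted = ndvi.values + 0.5
        if spec.tvi_form == "additive":
            vals, mask = shifted, ndvi.nodata_mask
        else:
            neg = shifted < 0
            vals = np.sqrt(np.where(neg, 0.0, shifted))
            mask = ndvi.nodata_mask | neg
    else:  # pragma: no cover - guarded by IndexSpec
        raise ValueError(name)
    vals = np.where(mask, 0.0, vals)
    return Grid(vals, geom, mask)


def onehot_landcover(
    classes_grid: Grid,
    class_names: Sequence[str],
    water_class: str | None = "Water",
) -> dict[str, Grid]:
    """Expand a categorical land-cover grid into binary bands, one per
    non-water class.

    ``classes_grid`` holds integer codes indexing ``class_names``. The water
    class (if listed) gets no band — water is handled by the water mask —
    so at every unmasked non-water cell the returned bands sum to exactly 1.
    """
    codes = classes_grid.values
    valid = classes_grid.valid
    int_codes = np.rint(codes).astype(int)
    observed = np.unique(int_codes[valid])
    known = set(range(len(class_names)))
    unknown = [c for c in observed if c not in known]
    if unknown:
        raise ValueError(f"unknown land-cover codes: {unknown}")
    out: dict[str, Grid] = {}
    for code, name in enumerate(class_names):
        if water_class is not None and name == water_class:
            continue
        band = ((int_codes == code) & valid).astype(np.float64)
        out[name] = Grid(band, classes_grid.geometry, classes_grid.nodata_mask.copy())
    return out


def assemble_stack(named_bands: Mapping[str, Grid]) -> PredictorStack:
    """Compile named bands into a PredictorStack with one unified nodata mask.

    Band order is the mapping's insertion order; geometry mismatches and
    duplicate names are rejected by the stack constructor.
    """
    return PredictorStack(dict(named_bands)).unify_masks()
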