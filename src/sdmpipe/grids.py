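"""Single-band grids, co-registered predictor stacks, and raster I/O.

All grids live on an axis-aligned, north-up, metric grid: row 0 is the
northernmost row, ``origin_x``/``origin_y`` are the map coordinates of the
top-left *corner*, and cells are half-open squares of side ``cell_size_m``.
A point (x, y) therefore belongs to ``col = floor((x - origin_x)/cell)``,
``row = floor((origin_y - y)/cell)``.

Rasters are read and written as GeoTIFFs: plain TIFF files carrying the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA)
plus a JSON image description holding the band names.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "GridGeometry",
    "PredictorStack",
    "read_raster",
    "read_stack",
    "write_raster",
    "apply_water_mask",
    "bilinear_resample",
    "temporal_median",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Shape, resolution and placement shared by co-registered grids."""

    n_rows: int
    n_cols: int
    cell_size_m: float
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edges."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size_m,
            self.origin_x + self.n_cols * self.cell_size_m,
            self.origin_y,
        )

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its (row, col); cells are half-open [edge, edge+cell)."""
        col = int(np.floor((x - self.origin_x) / self.cell_size_m))
        row = int(np.floor((self.origin_y - y) / self.cell_size_m))
        return row, col

    def contains_point(self, x: float, y: float) -> bool:
        row, col = self.point_to_cell(x, y)
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def cell_center(self, row, col):
        """Map coordinates of one or many cell centers (vectorised)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size_m
        y = self.origin_y - (row + 0.5) * self.cell_size_m
        return x, y

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (n_rows, n_cols) arrays of cell-center x and y coordinates."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)


@dataclass
class Grid:
    """A single-band raster: values plus a nodata mask on a `GridGeometry`.

    Masked cells are carried through every operation and never contribute
    to statistics, model fitting or sampling.
    """

    values: np.ndarray
    geometry: GridGeometry
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must match values")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def masked_values(self) -> np.ndarray:
        """Values at unmasked cells, flattened."""
        return self.values[self.valid]

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.nodata_mask] = fill
        return out

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.geometry, self.nodata_mask.copy())

    def equals(self, other: "Grid", atol: float = 0.0) -> bool:
        return (
            self.geometry == other.geometry
            and np.array_equal(self.nodata_mask, other.nodata_mask)
            and np.allclose(
                self.values[self.valid], other.values[other.valid], atol=atol, rtol=0.0
            )
        )


class PredictorStack:
    """Ordered, named, co-registered predictor bands sharing one geometry.

    Band order is insertion order. After `apply_water_mask` (or
    `unify_masks`) all bands share one nodata mask, so a cell is either
    usable in every predictor or in none.
    """

    def __init__(self, bands: Mapping[str, Grid]):
        if not bands:
            raise ValueError("a predictor stack needs at least one band")
        names = list(bands)
        if len(set(names)) != len(names):
            raise ValueError("duplicate band names")
        geom = next(iter(bands.values())).geometry
        for name, grid in bands.items():
            if grid.geometry != geom:
                raise ValueError(f"band {name!r} does not share the stack geometry")
        self._bands: dict[str, Grid] = {k: v for k, v in bands.items()}
        self.geometry = geom

    def __len__(self) -> int:
        return len(self._bands)

    def __contains__(self, name: str) -> bool:
        return name in self._bands

    def __getitem__(self, name: str) -> Grid:
        return self._bands[name]

    @property
    def band_names(self) -> list[str]:
        return list(self._bands)

    @property
    def bands(self) -> dict[str, Grid]:
        return dict(self._bands)

    def combined_mask(self) -> np.ndarray:
        """Union of all band nodata masks."""
        mask = np.zeros(self.geometry.shape, dtype=bool)
        for grid in self._bands.values():
            mask |= grid.nodata_mask
        return mask

    def unify_masks(self) -> "PredictorStack":
        """Return a stack where every band carries the union mask."""
        mask = self.combined_mask()
        return PredictorStack(
            {n: Grid(g.values.copy(), g.geometry, mask.copy()) for n, g in self._bands.items()}
        )

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid_cells, n_bands) matrix and flat indices of the valid cells.

        Valid means unmasked in every band; row order is row-major cell order.
        """
        mask = self.combined_mask()
        flat_idx = np.flatnonzero(~mask)
        cols = [g.values.ravel()[flat_idx] for g in self._bands.values()]
        return np.column_stack(cols), flat_idx

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_bands) matrix of band values at the given cells."""
        return np.column_stack([g.values[rows, cols] for g in self._bands.values()])


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(grid_or_stack, path, nodata: float = _DEFAULT_NODATA) -> Path:
    """Write a Grid or PredictorStack as a georeferenced multi-band GeoTIFF.

    Masked cells are stored as the nodata sentinel; band names go into a
    JSON image description.
    """
    path = Path(path)
    if isinstance(grid_or_stack, Grid):
        grids = {"band_1": grid_or_stack}
    elif isinstance(grid_or_stack, PredictorStack):
        grids = grid_or_stack.bands
    else:
        raise TypeError("expected Grid or PredictorStack")
    geom = next(iter(grids.values())).geometry
    data = np.stack([g.filled(nodata) for g in grids.values()])
    desc = json.dumps({"bands": list(grids), "crs": "local metric (projected, metres)"})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (geom.cell_size_m, geom.cell_size_m, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geom.origin_x, geom.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=desc,
        extratags=extratags,
        metadata=None,
    )
    return path


def _read_pages(path) -> tuple[np.ndarray, GridGeometry, float, list[str] | None]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        page = tf.pages[0]
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tiepoint = page.tags.get(_TAG_TIEPOINT)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path} has no georeferencing tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        _, _, _, ox, oy, _ = (float(v) for v in tiepoint.value[:6])
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else _DEFAULT_NODATA
        names = None
        desc_tag = page.tags.get(270)
        if desc_tag is not None:
            try:
                names = json.loads(desc_tag.value).get("bands")
            except (json.JSONDecodeError, AttributeError):
                names = None
    if data.ndim == 2:
        data = data[None]
    if not np.isclose(sx, sy):
        raise ValueError("anisotropic cells are not supported")
    geom = GridGeometry(data.shape[1], data.shape[2], sx, ox, oy)
    return data.astype(np.float64), geom, nodata, names


def read_raster(path):
    """Read a GeoTIFF; returns a Grid (single band) or list of Grids.

    The nodata sentinel recorded in the file is mapped into each band's
    nodata mask. Files without georeferencing tags are rejected.
    """
    data, geom, nodata, _ = _read_pages(path)
    grids = [
        Grid(band, geom, np.isclose(band, nodata) | ~np.isfinite(band)) for band in data
    ]
    return grids[0] if len(grids) == 1 else grids


def read_stack(path) -> PredictorStack:
    """Read a multi-band GeoTIFF into a PredictorStack, recovering band names."""
    data, geom, nodata, names = _read_pages(path)
    if names is None or len(names) != data.shape[0]:
        names = [f"band_{i + 1}" for i in range(data.shape[0])]
    return PredictorStack(
        {
            name: Grid(band, geom, np.isclose(band, nodata) | ~np.isfinite(band))
            for name, band in zip(names, data)
        }
    )


# ---------------------------------------------------------------------------
# Masking, resampling, compositing


def apply_water_mask(stack: PredictorStack, water: Grid) -> PredictorStack:
    """Mask every band of the stack wherever the water grid is truthy.

    The result carries one unified nodata mask (prior masks ∪ water), so
    no water cell can reach the classifier or the sampling stages.
    """
    if water.geometry != stack.geometry:
        raise ValueError("water mask does not share the stack geometry")
    water_bool = (water.values != 0) & water.valid
    mask = stack.combined_mask() | water_bool
    return PredictorStack(
        {n: Grid(g.values.copy(), g.geometry, mask.copy()) for n, g in stack.bands.items()}
    )


def bilinear_resample(coarse: Grid, target_geometry: GridGeometry) -> Grid:
    """Resample a coarse grid to a finer geometry by bilinear interpolation.

    Each target cell-center value is interpolated from the four surrounding
    coarse cell centers; within the outer half-cell ring of the coarse grid
    the interpolation degenerates to edge (constant) extrapolation. A target
    cell is masked if any coarse cell supporting it is masked — values are
    never fabricated next to missing data.
    """
    cg = coarse.geometry
    if cg.cell_size_m < target_geometry.cell_size_m:
        raise ValueError("coarse cell size must be >= target cell size")
    txmin, tymin, txmax, tymax = target_geometry.extent
    cxmin, cymin, cxmax, cymax = cg.extent
    eps = 1e-9 * cg.cell_size_m
    if txmin < cxmin - eps or txmax > cxmax + eps or tymin < cymin - eps or tymax > cymax + eps:
        raise ValueError("target extent lies outside the coarse grid")

    tx, ty = target_geometry.center_coords()
    # fractional position in the coarse *center* lattice
    u = (tx - (cg.origin_x + 0.5 * cg.cell_size_m)) / cg.cell_size_m
    v = ((cg.origin_y - 0.5 * cg.cell_size_m) - ty) / cg.cell_size_m
    u = np.clip(u, 0.0, cg.n_cols - 1.0)
    v = np.clip(v, 0.0, cg.n_rows - 1.0)
    c0 = np.clip(np.floor(u).astype(int), 0, max(cg.n_cols - 2, 0))
    r0 = np.clip(np.floor(v).astype(int), 0, max(cg.n_rows - 2, 0))
    c1 = np.minimum(c0 + 1, cg.n_cols - 1)
    r1 = np.minimum(r0 + 1, cg.n_rows - 1)
    fu = u - c0
    fv = v - r0

    z = coarse.values
    vals = (
        z[r0, c0] * (1 - fu) * (1 - fv)
        + z[r0, c1] * fu * (1 - fv)
        + z[r1, c0] * (1 - fu) * fv
        + z[r1, c1] * fu * fv
    )
    m = coarse.nodata_mask
    mask = m[r0, c0] | m[r0, c1] | m[r1, c0] | m[r1, c1]
    return Grid(vals, target_geometry, mask)


def temporal_median(grids: Sequence[Grid]) -> Grid:
    """Per-cell median across a sequence of co-registered grids.

    Masked values are ignored cell-wise; a cell is masked in the output only
    if it is masked in every input. Even counts use the mean of the central
    pair.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("temporal_median needs at least one grid")
    geom = grids[0].geometry
    for g in grids[1:]:
        if g.geometry != geom:
            raise ValueError("grids do not share a geometry")
    cube = np.stack([g.filled(np.nan) for g in grids])
    all_masked = np.all([g.nodata_mask for g in grids], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(cube, axis=0)
    med[all_masked] = 0.0
    return Grid(med, geom, all_masked)
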