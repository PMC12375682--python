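"""Presence-point handling: loading, point-to-cell mapping, spatial thinning.

Field presences are typically clustered (multiple GPS fixes per plant
patch); thinning to one randomly chosen record per raster cell removes
this pseudo-replication before modelling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridGeometry

__all__ = ["OccurrenceSet", "load_points", "thin_to_cells"]


@dataclass
class OccurrenceSet:
    """Presence (or pseudo-absence) point coordinates in map units."""

    points: np.ndarray  # (n, 2) of x, y

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    def cells(self, geometry: GridGeometry) -> np.ndarray:
        """(n, 2) integer array of (row, col) per point under the geometry."""
        if len(self.points) == 0:
            return np.zeros((0, 2), dtype=int)
        cols = np.floor((self.points[:, 0] - geometry.origin_x) / geometry.cell_size_m)
        rows = np.floor((geometry.origin_y - self.points[:, 1]) / geometry.cell_size_m)
        return np.column_stack([rows, cols]).astype(int)

    def to_csv(self, path, label: int | None = None) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.points, columns=["x", "y"])
        if label is not None:
            df["label"] = label
        df.to_csv(path, index=False)
        return path

    def to_geojson(self, path, label: int | None = None) -> Path:
        path = Path(path)
        props = {} if label is None else {"label": label}
        features = [
            {
                "type": "Feature",
                "properties": dict(props),
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            }
            for x, y in self.points
        ]
        path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
        return path


def load_points(path, geometry: GridGeometry | None = None) -> OccurrenceSet:
    """Load points from CSV (columns x, y) or GeoJSON Point features.

    If a geometry is given, points outside its extent are dropped with a
    warning reporting the count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".json", ".geojson"):
        obj = json.loads(path.read_text())
        feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
        coords = []
        for f in feats:
            geom = f.get("geometry", f)
            if geom.get("type") != "Point":
                raise ValueError("only Point features are supported")
            coords.append(tuple(geom["coordinates"][:2]))
        pts = np.array(coords, dtype=np.float64).reshape(-1, 2)
    else:
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "x" not in cols or "y" not in cols:
            raise ValueError(f"{path} lacks x/y columns")
        pts = df[[cols["x"], cols["y"]]].to_numpy(dtype=np.float64)
    if geometry is not None:
        xmin, ymin, xmax, ymax = geometry.extent
        inside = (
            (pts[:, 0] >= xmin) & (pts[:, 0] < xmax) & (pts[:, 1] > ymin) & (pts[:, 1] <= ymax)
        )
        dropped = int((~inside).sum())
        if dropped:
            warnings.warn(f"dropped {dropped} point(s) outside the grid extent", stacklevel=2)
        pts = pts[inside]
    return OccurrenceSet(pts)


def thin_to_cells(
    occ: OccurrenceSet, geometry: GridGeometry, seed: int | None = 0
) -> OccurrenceSet:
    """Thin to one randomly selected occurrence per occupied raster cell.

    The retained point in each multiply-occupied cell is chosen uniformly
    at random (seeded, hence reproducible); output size equals the number
    of distinct occupied cells and output order follows (row, col). Thinning
    an already-thinned set returns it unchanged.
    """
    if len(occ) == 0:
        warnings.warn("thinning an empty occurrence set", stacklevel=2)
        return OccurrenceSet(np.zeros((0, 2)))
    cells = occ.cells(geometry)
    rng = np.random.default_rng(seed)
    order = np.lexsort((cells[:, 1], cells[:, 0]))
    kept: list[int] = []
    i = 0
    while i < len(order):
        j = i
        while (
            j < len(order)
            and cells[order[j], 0] == cells[order[i], 0]
            and cells[order[j], 1] == cells[order[i], 1]
        ):
            j += 1
        group = order[i:j]
        kept.append(int(rng.choice(group)))
        i = j
    return OccurrenceSet(occ.points[kept])
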