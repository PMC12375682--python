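"""Build predictor bands from raw inputs: road buffers, radar dB,
vegetation indices and one-hot land cover.

Run:  python examples/build_predictor_stack.py
"""

import numpy as np

from sdmpipe import (
    GridGeometry,
    Grid,
    IndexSpec,
    PredictorStack,
    RoadNetwork,
    assemble_stack,
    buffer_rasterize_roads,
    compute_index,
    onehot_landcover,
    to_decibel,
)

geom = GridGeometry(n_rows=40, n_cols=40, cell_size_m=30.0, origin_x=0.0, origin_y=1200.0)
rng = np.random.default_rng(0)

# a road crossing the scene, buffered by 50 m and rasterised at cell centers
roads = RoadNetwork([[(0.0, 600.0), (600.0, 700.0), (1200.0, 500.0)]])
road_band = buffer_rasterize_roads(roads, buffer_m=50.0, geometry=geom)
print(f"road band: {int(road_band.values.sum())} of {geom.n_rows * geom.n_cols} "
      "cells within 50 m of the road")

# SAR backscatter arrives in linear power units; models use decibels
vv_linear = Grid(rng.uniform(0.01, 0.5, geom.shape), geom)
vv_db = to_decibel(vv_linear)
print(f"VV backscatter: linear median {np.median(vv_linear.values):.3f} "
      f"-> {np.median(vv_db.values):.1f} dB")

# vegetation indices from reflectance bands
reflectance = PredictorStack({
    "NIR": Grid(rng.uniform(0.2, 0.6, geom.shape), geom),
    "Red": Grid(rng.uniform(0.02, 0.2, geom.shape), geom),
    "Green": Grid(rng.uniform(0.05, 0.25, geom.shape), geom),
    "RE1": Grid(rng.uniform(0.1, 0.4, geom.shape), geom),
})
ndvi = compute_index(IndexSpec("NDVI"), reflectance)
savi = compute_index(IndexSpec("SAVI", L=0.5), reflectance)
print(f"NDVI mean {ndvi.values.mean():.3f} (in [-1, 1]); "
      f"SAVI(L=0.5) mean {savi.values.mean():.3f}")

# categorical land cover becomes one binary band per class
classes = ["Bare_Ground", "Bushland", "Forest", "Grassland", "Wetland", "Woodland"]
codes = Grid(rng.integers(0, 6, geom.shape).astype(float), geom)
lc = onehot_landcover(codes, classes, water_class=None)

stack = assemble_stack({
    "Roads": road_band, "VV": vv_db, "NDVI": ndvi, "SAVI_L05": savi, **lc,
})
print(f"assembled stack: {len(stack)} co-registered bands "
      f"({', '.join(stack.band_names[:4])}, ...)")
# The stack is the model's feature space: one value per band per land cell.
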