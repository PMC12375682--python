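"""Synthetic landscapes with known habitat-suitability truth.

The generator reproduces the statistical structure the pipeline assumes of
real satellite-derived inputs — spatially autocorrelated continuous
predictors, categorical land cover, a water mask, a road network rasterised
with a 50 m buffer, and presence points preferentially sampled along roads
(field access in a protected area is road-bound) from a known logistic
suitability surface — so every stage, including parameter recovery, is
testable without any downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import Grid, GridGeometry, PredictorStack
from .occurrences import OccurrenceSet
from .predictors import RoadNetwork, assemble_stack, buffer_rasterize_roads, onehot_landcover
from .grids import apply_water_mask

__all__ = [
    "SyntheticTruth",
    "LandscapeConfig",
    "gaussian_field",
    "synth_landscape",
    "sample_presences",
]

_LANDCOVER_CLASSES = ("Bare_Ground", "Bushland", "Forest", "Grassland", "Wetland", "Woodland")


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic landscape.

    ``suitability`` is the logistic surface
    sigmoid(β0 + Σ βj·zj + βr·road); presences are sampled from it with an
    optional road-access bias.
    """

    suitability: Grid
    informative_bands: list[str]
    coefficients: dict[str, float]
    road_coefficient: float
    sampling_bias_strength: float
    road_indicator: Grid


@dataclass
class LandscapeConfig:
    """Default synthetic scenario: a 200×200-cell landscape at 30 m with 20
    continuous predictors of which 3 are informative (β = 1.5, −1.0, 0.8),
    a road effect (β_road = 1.0), 6 land-cover classes, 5% water, and 400
    road-biased presences (bias strength 5)."""

    shape: tuple[int, int] = (200, 200)
    cell_size_m: float = 30.0
    n_bands: int = 20
    coefficients: dict[str, float] = field(
        default_factory=lambda: {"band_01": 1.5, "band_02": -1.0, "band_03": 0.8}
    )
    intercept: float = -1.0
    road_coefficient: float = 1.0
    road_buffer_m: float = 50.0
    correlation_length_cells: float = 8.0
    water_fraction: float = 0.05
    landcover_classes: tuple[str, ...] = _LANDCOVER_CLASSES
    sampling_bias_strength: float = 5.0
    n_presences: int = 400
    seed: int = 0


def gaussian_field(
    shape: tuple[int, int],
    correlation_length_cells: float,
    seed: int | None = 0,
    geometry: GridGeometry | None = None,
) -> Grid:
    """Standardized Gaussian random field.

    White noise is smoothed with a Gaussian kernel whose sigma is the
    correlation length (0 = no smoothing), then rescaled to mean 0 and
    population variance 1 over all cells. Deterministic per seed.
    """
    if correlation_length_cells < 0:
        raise ValueError("correlation length must be >= 0")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(shape)
    if correlation_length_cells > 0:
        z = gaussian_filter(z, sigma=correlation_length_cells, mode="reflect")
    z = (z - z.mean()) / z.std()
    if geometry is None:
        geometry = GridGeometry(shape[0], shape[1], 30.0)
    return Grid(z, geometry)


def _random_road(rng: np.random.Generator, geometry: GridGeometry) -> RoadNetwork:
    """A piecewise polyline crossing the extent west to east, plus a spur."""
    xmin, ymin, xmax, ymax = geometry.extent
    n_seg = 6
    xs = np.linspace(xmin, xmax, n_seg + 1)
    ys = rng.uniform(ymin + 0.15 * (ymax - ymin), ymax - 0.15 * (ymax - ymin), n_seg + 1)
    main = [(float(x), float(y)) for x, y in zip(xs, ys)]
    # spur from a midpoint toward the southern edge
    kx, ky = main[n_seg // 2]
    spur = [(kx, ky), (float(kx + rng.uniform(-0.1, 0.1) * (xmax - xmin)), float(ymin + 0.1 * (ymax - ymin)))]
    return RoadNetwork([main, spur])


def synth_landscape(
    config: LandscapeConfig = LandscapeConfig(),
) -> tuple[PredictorStack, SyntheticTruth, Grid, RoadNetwork]:
    """Generate (stack, truth, water, roads) for a synthetic scenario.

    The stack holds the continuous bands, the one-hot land-cover bands and
    the binary road band, all water-masked. Suitability is the logistic
    combination of the informative standardized bands plus the road term.
    """
    rows, cols = config.shape
    geometry = GridGeometry(rows, cols, config.cell_size_m)
    unknown = set(config.coefficients) - {f"band_{i + 1:02d}" for i in range(config.n_bands)}
    if unknown:
        raise ValueError(f"informative bands not in the band roster: {sorted(unknown)}")
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_bands + 4)

    bands: dict[str, Grid] = {}
    for i in range(config.n_bands):
        name = f"band_{i + 1:02d}"
        bands[name] = gaussian_field(
            config.shape, config.correlation_length_cells, int(seeds[i]), geometry
        )

    # categorical land cover from an auxiliary smooth field, equal quantile bins
    aux = gaussian_field(config.shape, config.correlation_length_cells, int(seeds[-4]), geometry)
    n_classes = len(config.landcover_classes)
    edges = np.quantile(aux.values, np.linspace(0, 1, n_classes + 1)[1:-1])
    codes = np.digitize(aux.values, edges).astype(float)
    lc_bands = onehot_landcover(
        Grid(codes, geometry), list(config.landcover_classes), water_class=None
    )

    # water mask from another smooth field
    wfield = gaussian_field(config.shape, config.correlation_length_cells, int(seeds[-3]), geometry)
    if config.water_fraction > 0:
        thresh = np.quantile(wfield.values, config.water_fraction)
        water_bool = wfield.values <= thresh
    else:
        water_bool = np.zeros(config.shape, dtype=bool)
    water = Grid(water_bool.astype(float), geometry)

    road_rng = np.random.default_rng(int(seeds[-2]))
    roads = _random_road(road_rng, geometry)
    road_grid = buffer_rasterize_roads(roads, config.road_buffer_m, geometry)

    named = dict(bands)
    named.update(lc_bands)
    named["Roads"] = road_grid
    stack = apply_water_mask(assemble_stack(named), water)

    eta = np.full(config.shape, config.intercept)
    for name, beta in config.coefficients.items():
        eta = eta + beta * bands[name].values
    eta = eta + config.road_coefficient * road_grid.values
    suit = 1.0 / (1.0 + np.exp(-eta))
    suitability = Grid(suit, geometry, water_bool.copy())
    truth = SyntheticTruth(
        suitability=suitability,
        informative_bands=list(config.coefficients),
        coefficients=dict(config.coefficients),
        road_coefficient=config.road_coefficient,
        sampling_bias_strength=config.sampling_bias_strength,
        road_indicator=road_grid,
    )
    return stack, truth, water, roads


def sample_presences(
    truth: SyntheticTruth,
    n: int,
    seed: int | None = 0,
    bias: float | None = None,
) -> OccurrenceSet:
    """Draw presence points from the true suitability surface.

    Cells are drawn without replacement with probability proportional to
    suitability × (1 + bias·road), where road is the binary road-buffer
    indicator — emulating field sampling restricted to road-accessible
    terrain. Points sit at cell centers with sub-cell jitter. Water cells
    are never sampled.
    """
    if bias is None:
        bias = truth.sampling_bias_strength
    if n < 1:
        raise ValueError("n must be >= 1")
    geom = truth.suitability.geometry
    weight = truth.suitability.values * (1.0 + bias * truth.road_indicator.values)
    weight = np.where(truth.suitability.valid, weight, 0.0).ravel()
    candidates = np.flatnonzero(weight > 0)
    if n > len(candidates):
        raise ValueError(f"n={n} exceeds the {len(candidates)} candidate cells")
    p = weight[candidates] / weight[candidates].sum()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=False, p=p)
    rows, cols = np.divmod(chosen, geom.n_cols)
    x, y = geom.cell_center(rows, cols)
    jitter = rng.uniform(-0.49, 0.49, size=(n, 2)) * geom.cell_size_m
    return OccurrenceSet(np.column_stack([x + jitter[:, 0], y + jitter[:, 1]]))
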