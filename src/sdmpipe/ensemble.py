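"""Spatial-block cross-validated random-forest ensemble.

The core habitat model: presences and block-balanced pseudo-absences are
split 70/30 by contiguous spatial blocks (not by points, so spatially
autocorrelated neighbours cannot leak between training and validation), a
random-forest classifier is fitted per iteration, and ten iterations are
aggregated into a mean habitat-suitability index (HSI) surface, its
per-cell SD, a majority-vote binary map, and mean per-predictor relative
contributions (%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .grids import Grid, GridGeometry, PredictorStack
from .metrics import MetricSet, auc_pr, auc_roc, sens_spec, summarize_iterations
from .occurrences import OccurrenceSet
from .pseudoabsence import (
    cluster_environment,
    eligible_absence_cells,
    sample_pseudoabsences,
    standardize_environment,
)

__all__ = [
    "BlockLayout",
    "EnsembleConfig",
    "FittedClassifier",
    "EnsembleResult",
    "build_blocks",
    "partition_blocks",
    "extract_training_table",
    "fit_classifier",
    "predict_surface",
    "run_ensemble",
    "majority_vote",
    "aggregate_importance",
    "subset_predictors",
]


@dataclass
class BlockLayout:
    """Square spatial blocks tiling the grid; ids are row-major."""

    block_id: np.ndarray  # (n_rows, n_cols) int
    block_size_cells: int
    geometry: GridGeometry

    @property
    def n_blocks(self) -> int:
        return int(self.block_id.max()) + 1


def build_blocks(geometry: GridGeometry, block_size_cells: int) -> BlockLayout:
    """Tile the grid with block_size × block_size cell blocks (edge blocks
    truncated), deterministic row-major ids."""
    if block_size_cells < 1:
        raise ValueError("block_size_cells must be >= 1")
    rows, cols = np.mgrid[0 : geometry.n_rows, 0 : geometry.n_cols]
    n_block_cols = -(-geometry.n_cols // block_size_cells)
    ids = (rows // block_size_cells) * n_block_cols + cols // block_size_cells
    return BlockLayout(ids.astype(int), block_size_cells, geometry)


def partition_blocks(
    layout: BlockLayout,
    occupied_blocks: set[int],
    train_fraction: float = 0.7,
    seed: int | None = 0,
    presence_blocks: set[int] | None = None,
) -> dict[int, str]:
    """Randomly assign data-bearing blocks to train/validation.

    The train share of occupied blocks is round(train_fraction · n). When
    ``presence_blocks`` is given, the draw is repeated (seed incremented,
    at most 100 tries) until both partitions hold at least one
    presence-bearing block, so every iteration can be validated.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    blocks = np.array(sorted(occupied_blocks), dtype=int)
    n = len(blocks)
    if n < 2:
        raise ValueError("need at least two occupied blocks to partition")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    presence_blocks = presence_blocks if presence_blocks is not None else set(blocks.tolist())
    base = 0 if seed is None else int(seed)
    for attempt in range(100):
        rng = np.random.default_rng(base + attempt)
        train = set(rng.choice(blocks, size=n_train, replace=False).tolist())
        has_train = any(b in train for b in presence_blocks)
        has_val = any(b not in train for b in presence_blocks)
        if has_train and has_val:
            return {int(b): ("train" if b in train else "validation") for b in blocks}
    raise ValueError("could not place presences in both partitions within 100 tries")


def extract_training_table(
    stack: PredictorStack,
    presences: OccurrenceSet,
    pseudoabsences: OccurrenceSet,
    layout: BlockLayout,
    partition: dict[int, str],
) -> pd.DataFrame:
    """One row per point: all band values, label, block id, partition.

    Points on masked cells are dropped with a warning.
    """
    mask = stack.combined_mask()
    frames = []
    for occ, label in ((presences, 1), (pseudoabsences, 0)):
        if len(occ) == 0:
            continue
        cells = occ.cells(stack.geometry)
        rows, cols = cells[:, 0], cells[:, 1]
        ok = (
            (rows >= 0)
            & (rows < stack.geometry.n_rows)
            & (cols >= 0)
            & (cols < stack.geometry.n_cols)
        )
        ok &= ~mask[np.clip(rows, 0, stack.geometry.n_rows - 1),
                    np.clip(cols, 0, stack.geometry.n_cols - 1)]
        if (~ok).any():
            warnings.warn(
                f"dropped {int((~ok).sum())} point(s) on masked or out-of-grid cells",
                stacklevel=2,
            )
        rows, cols = rows[ok], cols[ok]
        X = stack.values_at_cells(rows, cols)
        df = pd.DataFrame(X, columns=stack.band_names)
        df["label"] = label
        df["block_id"] = layout.block_id[rows, cols]
        df["row"] = rows
        df["col"] = cols
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table["partition"] = table["block_id"].map(partition)
    return table


@dataclass
class FittedClassifier:
    """A seeded bagged-decision-tree ensemble with impurity importances."""

    model: RandomForestClassifier
    feature_names: list[str]

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        prob = self.model.predict_proba(np.asarray(X, dtype=float))
        pos_col = int(np.flatnonzero(self.model.classes_ == 1)[0])
        return prob[:, pos_col]

    @property
    def importances(self) -> np.ndarray:
        return self.model.feature_importances_


def fit_classifier(
    train_rows: pd.DataFrame,
    n_trees: int = 500,
    seed: int | None = 0,
    feature_names: list[str] | None = None,
) -> FittedClassifier:
    """Fit a random forest on the training rows of a training table.

    Deterministic for a fixed seed; exposes class-1 probabilities and
    impurity-based importances. Both labels must be present.
    """
    if feature_names is None:
        feature_names = [
            c for c in train_rows.columns if c not in ("label", "block_id", "partition", "row", "col")
        ]
    y = train_rows["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    X = train_rows[feature_names].to_numpy(dtype=float)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return FittedClassifier(rf, list(feature_names))


def predict_surface(
    model: FittedClassifier, stack: PredictorStack, threshold: float = 0.5
) -> tuple[Grid, Grid]:
    """Per-cell presence probability and thresholded binary surfaces.

    Masked cells propagate to both outputs; binary = 1 iff probability
    >= threshold.
    """
    missing = [n for n in model.feature_names if n not in stack]
    if missing:
        raise KeyError(f"stack lacks band(s) required by the model: {missing}")
    sub = PredictorStack({n: stack[n] for n in model.feature_names})
    X, flat_idx = sub.to_matrix()
    prob_flat = model.predict_probability(X)
    geom = stack.geometry
    mask = sub.combined_mask()
    prob = np.zeros(geom.shape)
    prob.ravel()[flat_idx] = prob_flat
    binary = np.zeros(geom.shape)
    binary.ravel()[flat_idx] = (prob_flat >= threshold).astype(float)
    return Grid(prob, geom, mask.copy()), Grid(binary, geom, mask.copy())


def majority_vote(binary_grids) -> Grid:
    """Binary aggregation across iterations: 1 iff strictly more than half
    of the unmasked votes at a cell are 1 (so an exact 5-5 tie over ten
    iterations yields absence)."""
    grids = list(binary_grids)
    if not grids:
        raise ValueError("majority_vote needs at least one grid")
    geom = grids[0].geometry
    ones = np.zeros(geom.shape)
    valid = np.zeros(geom.shape)
    for g in grids:
        if g.geometry != geom:
            raise ValueError("grids do not share a geometry")
        ones += np.where(g.valid, g.values, 0.0)
        valid += g.valid
    out = (ones > valid / 2.0).astype(float)
    mask = valid == 0
    out[mask] = 0.0
    return Grid(out, geom, mask)


def aggregate_importance(importances) -> dict[str, float]:
    """Mean relative contribution (%) per predictor across iterations.

    Each iteration's raw importance vector is normalised to sum 100, then
    averaged, so the output also sums to 100.
    """
    importances = list(importances)
    if not importances:
        raise ValueError("no importance vectors")
    keys = list(importances[0].keys()) if isinstance(importances[0], dict) else None
    mats = []
    for vec in importances:
        arr = np.array([vec[k] for k in keys] if keys else vec, dtype=float)
        if (arr < 0).any():
            raise ValueError("importances must be non-negative")
        total = arr.sum()
        if total <= 0:
            raise ValueError("zero importance vector")
        mats.append(100.0 * arr / total)
    mean = np.mean(mats, axis=0)
    if keys is None:
        keys = [f"feature_{i}" for i in range(len(mean))]
    return {k: float(v) for k, v in zip(keys, mean)}


def subset_predictors(
    mean_importance_percent: dict[str, float], threshold: float = 3.5
) -> list[str]:
    """Predictor names whose mean relative contribution exceeds the
    threshold (%), sorted by decreasing contribution."""
    kept = sorted(
        (name for name, v in mean_importance_percent.items() if v > threshold),
        key=lambda n: -mean_importance_percent[n],
    )
    if not kept:
        warnings.warn(f"no predictor exceeds the {threshold}% threshold", stacklevel=2)
    return kept


@dataclass
class EnsembleConfig:
    """Tunable parameters of the ensemble run.

    ``k_clusters`` controls the environmental-profiling resolution. It must
    be fine enough that clusters free of presences exist — with a coarse
    partition every cluster is occupied and pseudo-absences degenerate to
    background draws. The default suits presence sets of a few hundred
    points (roughly presence count / 3 clusters); it is clamped for small
    landscapes.
    """

    n_iterations: int = 10
    train_fraction: float = 0.7
    n_trees: int = 500
    block_size_cells: int = 10
    k_clusters: int = 150
    binary_threshold: float = 0.5
    importance_threshold: float = 3.5
    seed: int = 0


@dataclass
class EnsembleResult:
    """Per-iteration surfaces and metrics plus their aggregates."""

    probability_grids: list[Grid]
    binary_grids: list[Grid]
    importance_vectors: list[dict[str, float]]
    metric_sets: list[MetricSet]
    hsi_mean: Grid = field(default=None)  # type: ignore[assignment]
    hsi_sd: Grid = field(default=None)  # type: ignore[assignment]
    majority_binary: Grid = field(default=None)  # type: ignore[assignment]
    mean_importance_percent: dict[str, float] = field(default_factory=dict)
    metric_summary: dict[str, dict[str, float]] = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    def aggregate(self) -> "EnsembleResult":
        geom = self.probability_grids[0].geometry
        cube = np.stack([g.values for g in self.probability_grids])
        mask = self.probability_grids[0].nodata_mask.copy()
        self.hsi_mean = Grid(np.where(mask, 0.0, cube.mean(axis=0)), geom, mask.copy())
        self.hsi_sd = Grid(np.where(mask, 0.0, cube.std(axis=0)), geom, mask.copy())
        self.majority_binary = majority_vote(self.binary_grids)
        self.mean_importance_percent = aggregate_importance(self.importance_vectors)
        self.metric_summary = summarize_iterations(self.metric_sets)
        return self


def _evaluate_partition(
    table: pd.DataFrame, model: FittedClassifier, threshold: float
) -> MetricSet:
    val = table[table["partition"] == "validation"]
    X = val[model.feature_names].to_numpy(dtype=float)
    y = val["label"].to_numpy(dtype=int)
    scores = model.predict_probability(X)
    pred = (scores >= threshold).astype(int)
    sens, spec = sens_spec(pred, y)
    return MetricSet(
        auc_roc=auc_roc(scores, y),
        auc_pr=auc_pr(scores, y),
        sensitivity=sens,
        specificity=spec,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


def run_ensemble(
    stack: PredictorStack,
    presences: OccurrenceSet,
    config: EnsembleConfig = EnsembleConfig(),
) -> EnsembleResult:
    """Run the full cross-validated ensemble on a water-masked stack and
    (already thinned) presence points.

    Environmental profiling (standardisation + k-means) is done once; each
    of the ``n_iterations`` iterations then draws its own block-balanced
    pseudo-absences, its own 70/30 block partition, fits a seeded forest,
    predicts the full suitability surface and is evaluated on its
    validation partition. Iteration seeds are ``config.seed + i``.
    """
    stack = stack.unify_masks()
    geom = stack.geometry
    mask = stack.combined_mask()

    cells = presences.cells(geom)
    on_grid = (
        (cells[:, 0] >= 0)
        & (cells[:, 0] < geom.n_rows)
        & (cells[:, 1] >= 0)
        & (cells[:, 1] < geom.n_cols)
    )
    rows = np.clip(cells[:, 0], 0, geom.n_rows - 1)
    cols = np.clip(cells[:, 1], 0, geom.n_cols - 1)
    usable = on_grid & ~mask[rows, cols]
    if (~usable).any():
        warnings.warn(
            f"dropped {int((~usable).sum())} presence point(s) on masked cells",
            stacklevel=2,
        )
    presences = OccurrenceSet(presences.points[usable])
    cells = cells[usable]
    presence_flat = set((cells[:, 0] * geom.n_cols + cells[:, 1]).tolist())

    table = standardize_environment(stack)
    k = config.k_clusters
    max_k = max(2, table.values.shape[0] // 10)
    if k > max_k:
        warnings.warn(
            f"k_clusters={k} too large for {table.values.shape[0]} cells; using {max_k}",
            stacklevel=2,
        )
        k = max_k
    cluster = cluster_environment(table, k, seed=config.seed)
    eligible = eligible_absence_cells(cluster, presence_flat)

    layout = build_blocks(geom, config.block_size_cells)
    block_flat = layout.block_id.ravel()
    presence_blocks_arr = layout.block_id[cells[:, 0], cells[:, 1]]
    counts: dict[int, int] = {}
    for b in presence_blocks_arr:
        counts[int(b)] = counts.get(int(b), 0) + 1
    presence_blocks = set(counts)

    result = EnsembleResult([], [], [], [], seeds=[])
    for i in range(config.n_iterations):
        seed_i = config.seed + i
        try:
            pas = sample_pseudoabsences(eligible, block_flat, counts, geom, seed=seed_i)
            pa_cells = pas.cells(geom)
            occupied = presence_blocks | set(
                layout.block_id[pa_cells[:, 0], pa_cells[:, 1]].tolist()
            )
            partition = partition_blocks(
                layout, occupied, config.train_fraction, seed=seed_i,
                presence_blocks=presence_blocks,
            )
            train_table = extract_training_table(stack, presences, pas, layout, partition)
            model = fit_classifier(
                train_table[train_table["partition"] == "train"],
                n_trees=config.n_trees,
                seed=seed_i,
                feature_names=stack.band_names,
            )
            prob, binary = predict_surface(model, stack, threshold=config.binary_threshold)
            metrics = _evaluate_partition(train_table, model, config.binary_threshold)
        except Exception as exc:
            raise RuntimeError(f"ensemble iteration {i} (seed {seed_i}) failed") from exc
        result.probability_grids.append(prob)
        result.binary_grids.append(binary)
        result.importance_vectors.append(
            dict(zip(model.feature_names, model.importances))
        )
        result.metric_sets.append(metrics)
        result.seeds.append(seed_i)
    return result.aggregate()
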