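"""Pseudo-absence generation by environmental profiling.

With presence-only field data the model needs artificial absences. The
two-step profiling used here: (1) presence cells are masked out, and
(2) the landscape's environmental space (all standardized predictor bands)
is k-means clustered; cells in clusters containing no presence are taken
to be "environmentally distinct" from occupied habitat and form the
eligible pool. Pseudo-absences are then drawn per spatial block to match
the block's presence count, keeping the training data balanced both
globally and spatially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .grids import GridGeometry, PredictorStack
from .occurrences import OccurrenceSet

__all__ = [
    "EnvironmentTable",
    "ClusterModel",
    "standardize_environment",
    "cluster_environment",
    "eligible_absence_cells",
    "sample_pseudoabsences",
]


@dataclass
class EnvironmentTable:
    """Standardized environmental values, one row per unmasked cell.

    ``values`` holds z-scores (per-band mean 0, population variance 1 over
    the rows); ``cell_indices`` are flat row-major cell indices into the
    grid; masked (incl. water) cells never appear.
    """

    values: np.ndarray
    cell_indices: np.ndarray
    band_names: list[str]
    geometry: GridGeometry


@dataclass
class ClusterModel:
    """A fitted k-means partition of environmental space."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray  # cluster id per EnvironmentTable row
    cell_indices: np.ndarray  # flat cell index per row
    inertia: float


def standardize_environment(stack: PredictorStack) -> EnvironmentTable:
    """Z-score every band over the unmasked cells (population SD).

    Constant bands carry no clustering information and are dropped with a
    warning.
    """
    X, flat_idx = stack.to_matrix()
    if X.shape[0] < 2:
        raise ValueError("need at least two unmasked cells to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD (ddof=0)
    keep = sd > 0
    names = stack.band_names
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropped constant band(s): {dropped}", stacklevel=2)
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    return EnvironmentTable(
        Z, flat_idx, [n for n, k in zip(names, keep) if k], stack.geometry
    )


def cluster_environment(table: EnvironmentTable, k: int, seed: int | None = 0) -> ClusterModel:
    """Partition environmental space with k-means (Euclidean distance in
    standardized space; k-means++ seeding, 5 restarts, best inertia).
    """
    n = table.values.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=5, max_iter=100, tol=1e-6, random_state=seed)
    labels = km.fit_predict(table.values)
    return ClusterModel(k, km.cluster_centers_, labels, table.cell_indices, float(km.inertia_))


def eligible_absence_cells(
    model: ClusterModel,
    presence_cells: set[int],
    water_cells: set[int] | None = None,
) -> set[int]:
    """Flat cell indices eligible to host pseudo-absences.

    Eligible cells (a) are not presence cells and (b) lie in clusters with
    no presence member. If *every* cluster contains a presence, the rule
    falls back to clusters whose presence fraction is below the global
    presence fraction. Presence and water cells are never eligible.
    """
    water_cells = water_cells or set()
    cell_to_label = dict(zip(model.cell_indices.tolist(), model.labels.tolist()))
    present = [c for c in presence_cells if c in cell_to_label]
    presence_per_cluster = np.zeros(model.k, dtype=int)
    for c in present:
        presence_per_cluster[cell_to_label[c]] += 1
    cluster_sizes = np.bincount(model.labels, minlength=model.k)

    empty = presence_per_cluster == 0
    if empty.any():
        ok_clusters = set(np.flatnonzero(empty).tolist())
    else:
        global_frac = len(present) / len(model.cell_indices)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = presence_per_cluster / np.maximum(cluster_sizes, 1)
        ok_clusters = set(np.flatnonzero(frac < global_frac).tolist())
        warnings.warn(
            "every cluster contains presences; falling back to "
            "below-average presence density clusters",
            stacklevel=2,
        )
    eligible = {
        int(c)
        for c, lab in zip(model.cell_indices, model.labels)
        if lab in ok_clusters and int(c) not in presence_cells and int(c) not in water_cells
    }
    if not eligible:
        raise ValueError(
            "no eligible pseudo-absence cells; increase k or relax the profiling rule"
        )
    return eligible


def sample_pseudoabsences(
    eligible: set[int],
    block_ids: np.ndarray,
    presence_counts_per_block: dict[int, int],
    geometry: GridGeometry,
    seed: int | None = 0,
) -> OccurrenceSet:
    """Draw pseudo-absence cells block-balanced against the presence counts.

    For each block with ``p`` presences, ``p`` cells are drawn uniformly
    without replacement from the eligible cells of that block; a block-level
    shortfall is made up from the global eligible pool with a warning.
    Points are placed at cell centers. The total equals the total presence
    count; a global shortfall raises.
    """
    rng = np.random.default_rng(seed)
    block_flat = np.asarray(block_ids).ravel()
    total_needed = sum(presence_counts_per_block.values())
    if total_needed > len(eligible):
        raise ValueError(
            f"only {len(eligible)} eligible cells for {total_needed} pseudo-absences"
        )
    eligible_arr = np.fromiter(eligible, dtype=int)
    eligible_arr.sort()  # determinism independent of set iteration order
    chosen: list[int] = []
    taken = np.zeros(len(eligible_arr), dtype=bool)
    cell_blocks = block_flat[eligible_arr]
    shortfall = 0
    for block, p in sorted(presence_counts_per_block.items()):
        if p <= 0:
            continue
        avail = np.flatnonzero((cell_blocks == block) & ~taken)
        take = min(p, len(avail))
        if take:
            pick = rng.choice(avail, size=take, replace=False)
            taken[pick] = True
            chosen.extend(eligible_arr[pick].tolist())
        shortfall += p - take
    if shortfall:
        warnings.warn(
            f"{shortfall} pseudo-absence(s) drawn from the global pool "
            "(block-level eligible cells exhausted)",
            stacklevel=2,
        )
        avail = np.flatnonzero(~taken)
        pick = rng.choice(avail, size=shortfall, replace=False)
        chosen.extend(eligible_arr[pick].tolist())
    chosen_arr = np.array(chosen, dtype=int)
    rows, cols = np.divmod(chosen_arr, geometry.n_cols)
    x, y = geometry.cell_center(rows, cols)
    return OccurrenceSet(np.column_stack([x, y]))
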