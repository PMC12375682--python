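import numpy as np
import pytest

from sdmpipe import (
    EnsembleConfig,
    Grid,
    GridGeometry,
    run_ensemble,
    sample_presences,
    synth_landscape,
    thin_to_cells,
)
from sdmpipe.simulate import LandscapeConfig


def make_grid(values, cell=30.0, origin=(0.0, 0.0), mask=None):
    values = np.asarray(values, dtype=float)
    geom = GridGeometry(values.shape[0], values.shape[1], cell, origin[0], origin[1])
    return Grid(values, geom, mask)


@pytest.fixture(scope="session")
def small_scene():
    """A compact synthetic scene: 60x60 landscape, 120 thinned presences."""
    cfg = LandscapeConfig(shape=(60, 60), n_presences=120, seed=11)
    stack, truth, water, roads = synth_landscape(cfg)
    presences = sample_presences(truth, cfg.n_presences, seed=12)
    presences = thin_to_cells(presences, stack.geometry, seed=13)
    return {"config": cfg, "stack": stack, "truth": truth, "water": water,
            "roads": roads, "presences": presences}


@pytest.fixture(scope="session")
def small_ensemble(small_scene):
    """A fast ensemble run on the small scene (reduced forest size)."""
    cfg = EnsembleConfig(n_trees=50, k_clusters=40, seed=21)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_ensemble(small_scene["stack"], small_scene["presences"], cfg)
    return result
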