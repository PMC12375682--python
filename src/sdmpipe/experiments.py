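"""Reference experiments: parameter recovery on the default synthetic
scenario and the published-area accounting.

These are the package's own benchmark computations, shared by the test
suite, the acceptance script and the examples so they are always computed
the same way.
"""

from __future__ import annotations

from .change import AKAGERA_SUITABLE_KM2, AKAGERA_TOTAL_KM2, AreaSummary, area_summary
from .ensemble import EnsembleConfig, run_ensemble
from .occurrences import thin_to_cells
from .simulate import LandscapeConfig, sample_presences, synth_landscape

__all__ = ["TRUE_DRIVERS", "recovery_replicate", "akagera_area_summary"]

#: Predictors with nonzero effect in the default synthetic scenario.
TRUE_DRIVERS = ("band_01", "band_02", "band_03", "Roads")


def recovery_replicate(seed: int, config: EnsembleConfig | None = None) -> dict:
    """Run one parameter-recovery replicate of the default scenario.

    Generates the default synthetic landscape with the given seed, samples
    and thins the road-biased presences, runs the full cross-validated
    ensemble, and reports validation metrics plus whether all true drivers
    (three informative bands and the road layer) rank in the top five of
    mean importance.
    """
    land = LandscapeConfig(seed=seed)
    stack, truth, water, roads = synth_landscape(land)
    presences = sample_presences(truth, land.n_presences, seed=seed + 1)
    presences = thin_to_cells(presences, stack.geometry, seed=seed + 2)
    if config is None:
        config = EnsembleConfig(seed=seed)
    result = run_ensemble(stack, presences, config)
    ranked = sorted(result.mean_importance_percent.items(), key=lambda kv: -kv[1])
    top5 = [name for name, _ in ranked[:5]]
    return {
        "seed": seed,
        "n_presences": len(presences),
        "mean_auc_roc": result.metric_summary["auc_roc"]["mean"],
        "mean_auc_pr": result.metric_summary["auc_pr"]["mean"],
        "mean_sensitivity": result.metric_summary["sensitivity"]["mean"],
        "mean_specificity": result.metric_summary["specificity"]["mean"],
        "top5": top5,
        "drivers_in_top5": all(d in top5 for d in TRUE_DRIVERS),
        "result": result,
    }


def akagera_area_summary() -> AreaSummary:
    """Area accounting for the published annual suitable-habitat series."""
    return area_summary(AKAGERA_SUITABLE_KM2, AKAGERA_TOTAL_KM2)
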