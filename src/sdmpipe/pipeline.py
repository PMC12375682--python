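"""End-to-end orchestration: simulate/load → thin → profile → ensemble →
evaluate → change, with a reproducibility manifest.

A run is fully described by a `RunConfig` (one YAML/JSON file); every
random stage derives its seed from the master seed, so two runs with the
same config produce identical metrics and probability rasters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .change import area_summary, hsi_change
from .ensemble import EnsembleConfig, EnsembleResult, run_ensemble
from .grids import Grid, read_raster, read_stack, write_raster
from .occurrences import OccurrenceSet, load_points, thin_to_cells
from .simulate import LandscapeConfig, sample_presences, synth_landscape
from .grids import apply_water_mask

logger = logging.getLogger("sdmpipe")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With ``synthetic=True`` the landscape and presences are generated
    (one landscape per entry in ``years``, each with its own derived
    seed); otherwise ``stack_path``/``points_path``/``water_path`` name
    the inputs of a single-year run.
    """

    output_dir: str = "sdm_output"
    seed: int = 0
    synthetic: bool = True
    years: list[int] = field(default_factory=lambda: [0])
    landscape: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    stack_path: str | None = None
    points_path: str | None = None
    water_path: str | None = None
    total_km2: float | None = None
    thinning: bool = True
    write_iteration_layers: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        obj = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def ensemble_config(self, seed: int) -> EnsembleConfig:
        return EnsembleConfig(**{**self.ensemble, "seed": seed})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _year_inputs(config: RunConfig, year_index: int, year: int):
    """(stack, presences) for one year, synthetic or from files."""
    if config.synthetic:
        land_seed = config.seed + 1000 * (year_index + 1)
        lc = LandscapeConfig(**{**config.landscape, "seed": land_seed})
        stack, truth, water, roads = synth_landscape(lc)
        presences = sample_presences(truth, lc.n_presences, seed=land_seed + 1)
        logger.info("year %s: simulated %d-band stack, %d presences", year, len(stack), len(presences))
        return stack, presences
    stack = read_stack(config.stack_path)
    if config.water_path:
        stack = apply_water_mask(stack, read_raster(config.water_path))
    presences = load_points(config.points_path, stack.geometry)
    logger.info("year %s: loaded %d-band stack, %d presences", year, len(stack), len(presences))
    return stack, presences


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the output manifest.

    Per year: thin presences, run the cross-validated ensemble, write the
    HSI mean/SD and majority-vote rasters plus metrics and importance
    CSVs. With two or more years, a change map (last − first) and an
    annual area summary are added. The manifest echoes the config, lists
    every seed used, and records a sha256 per output file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "years": {},
        "files": {},
        "status": "incomplete",
    }
    results: dict[int, EnsembleResult] = {}
    try:
        for idx, year in enumerate(config.years):
            stack, presences = _year_inputs(config, idx, year)
            run_seed = config.seed + 1000 * (idx + 1)
            if config.thinning:
                before = len(presences)
                presences = thin_to_cells(presences, stack.geometry, seed=run_seed + 2)
                logger.info("year %s: thinned %d -> %d presences", year, before, len(presences))
            ens = run_ensemble(stack, presences, config.ensemble_config(run_seed))
            results[year] = ens
            tag = f"_{year}" if len(config.years) > 1 else ""
            files = {
                f"hsi_mean{tag}.tif": lambda p, e=ens: write_raster(e.hsi_mean, p),
                f"hsi_sd{tag}.tif": lambda p, e=ens: write_raster(e.hsi_sd, p),
                f"majority_binary{tag}.tif": lambda p, e=ens: write_raster(e.majority_binary, p),
            }
            for name, writer in files.items():
                writer(out / name)
            _write_metrics_csv(ens, out / f"metrics{tag}.csv")
            _write_importance_csv(ens, out / f"importance{tag}.csv")
            manifest["years"][str(year)] = {
                "n_presences": len(presences),
                "seeds": ens.seeds,
                "metric_summary": ens.metric_summary,
            }
        if len(config.years) >= 2:
            first, last = config.years[0], config.years[-1]
            cm = hsi_change(results[first].hsi_mean, results[last].hsi_mean, first, last)
            write_raster(cm.delta, out / f"hsi_change_{first}_{last}.tif")
            total = config.total_km2
            if total is None:
                g = results[first].majority_binary.geometry
                total = g.n_rows * g.n_cols * (g.cell_size_m / 1000.0) ** 2
            summ = area_summary(
                {y: results[y].majority_binary for y in config.years}, total
            )
            summ.table.to_csv(out / "area_summary.csv", index=False)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _write_metrics_csv(ens: EnsembleResult, path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "iteration": i,
            "seed": ens.seeds[i],
            "auc_roc": m.auc_roc,
            "auc_pr": m.auc_pr,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "n_pos": m.n_pos,
            "n_neg": m.n_neg,
        }
        for i, m in enumerate(ens.metric_sets)
    ]
    summary = {"iteration": "mean"}
    summary.update({k: v["mean"] for k, v in ens.metric_summary.items()})
    sd_row = {"iteration": "sd"}
    sd_row.update({k: v["sd"] for k, v in ens.metric_summary.items()})
    pd.DataFrame(rows + [summary, sd_row]).to_csv(path, index=False)


def _write_importance_csv(ens: EnsembleResult, path: Path) -> None:
    import pandas as pd

    items = sorted(ens.mean_importance_percent.items(), key=lambda kv: -kv[1])
    pd.DataFrame(items, columns=["predictor", "mean_importance_percent"]).to_csv(
        path, index=False
    )
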