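"""Pipeline orchestration: simulate/load -> VIF screen -> spatial Gini ->
emerging hotspots -> STVC fit -> STVPI, with manifest logging and a
consolidated JSON report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .gini import (
    gini_by_region_year,
    gini_trends_by_region,
    region_mean_totals,
    summarize_trends,
)
from .hotspots import (
    classify_emerging_pattern,
    gi_star_cube,
    patterns_to_dataframe,
    summarize_patterns,
)
from .panel import read_gal, read_panel_csv, vif_screen, write_gal, write_panel_csv
from .simulate import SimulationConfig, simulate_panel
from .stvc import STVCSpec, build_stvc, extract_sc_tc, fit_stvc
from .stvpi import compute_stvpi, rank_determinants

log = logging.getLogger("geotriad")

ALL_STAGES = ("screen", "gini", "hotspots", "stvc", "stvpi")


@dataclass
class RunConfig:
    """One run: either a simulation config or input file paths, stage
    toggles and per-stage parameters.  The seed governs simulation and
    MCMC and is recorded in the manifest."""

    out_dir: str
    simulation: SimulationConfig | None = None
    panel_csv: str | None = None
    weights_gal: str | None = None
    stages: tuple = ALL_STAGES
    alpha: float = 0.05
    temporal_window: int = 0
    vif_threshold: float = 5.0
    cumulative_threshold: float = 84.0
    mcmc: STVCSpec = field(default_factory=STVCSpec)
    seed: int = 0

    def __post_init__(self):
        has_sim = self.simulation is not None
        has_files = self.panel_csv is not None and self.weights_gal is not None
        if has_sim == has_files:
            raise ValueError("provide exactly one of: simulation config, input paths")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = STVCSpec(**d["mcmc"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the report dict.

    Every stage writes its own artifacts under ``config.out_dir``; a
    failure halts the pipeline (partial outputs are retained) with the
    stage name in the raised error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    report: dict = {"stages_run": [], "warnings": []}
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": list(config.stages),
        "temporal_window": config.temporal_window,
        "alpha": config.alpha,
    }
    stage = "input"
    try:
        if config.simulation is not None:
            sim = config.simulation
            sim.seed = config.seed
            panel, weights, truth = simulate_panel(sim)
            write_panel_csv(panel, out / "panel.csv")
            write_gal(weights, out / "weights.gal")
            _dump(
                {k: v for k, v in truth.items() if k != "response"},
                out / "truth.json",
            )
            manifest["input"] = "simulated"
        else:
            panel = read_panel_csv(config.panel_csv)
            weights = read_gal(config.weights_gal)
            manifest["input"] = {"panel": config.panel_csv, "weights": config.weights_gal}
        log.info("panel: %d areas x %d years", panel.n_areas, panel.n_years)

        covariates = list(panel.covariate_names)
        if "screen" in config.stages and panel.n_covariates >= 2:
            stage = "screen"
            flat = panel.covariates.reshape(-1, panel.n_covariates)
            import pandas as pd

            tab = pd.DataFrame(flat, columns=covariates)
            retained, vifs, dropped = vif_screen(tab, threshold=config.vif_threshold)
            covariates = retained
            report["vif"] = {"retained": retained, "vif": vifs, "dropped": dropped}
            _dump(report["vif"], out / "vif.json")
            report["stages_run"].append(stage)

        if "gini" in config.stages:
            stage = "gini"
            import warnings as _w

            with _w.catch_warnings(record=True) as caught:
                _w.simplefilter("always")
                decomp = gini_by_region_year(panel, weights)
            report["warnings"] += [str(w.message) for w in caught]
            trends = gini_trends_by_region(decomp, alpha=config.alpha)
            decomp.to_csv(out / "gini.csv", index=False, float_format="%.17g")
            region_mean_totals(decomp).to_csv(
                out / "gini_region_means.csv", index=False, float_format="%.17g"
            )
            trends.to_csv(out / "gini_trends.csv", index=False, float_format="%.17g")
            report["gini_trends"] = summarize_trends(trends)
            _dump(report["gini_trends"], out / "gini_summary.json")
            report["stages_run"].append(stage)

        if "hotspots" in config.stages:
            stage = "hotspots"
            cube = gi_star_cube(panel, weights, temporal_window=config.temporal_window)
            results = classify_emerging_pattern(cube, panel.area_ids, alpha=config.alpha)
            pdf = patterns_to_dataframe(results)
            pdf.to_csv(out / "hotspots.csv", index=False, float_format="%.17g")
            import pandas as pd

            zdf = pd.DataFrame(
                cube.z, index=panel.area_ids, columns=[int(y) for y in panel.years]
            )
            zdf.to_csv(out / "hotspots_z.csv", float_format="%.17g")
            report["hotspots"] = summarize_patterns(results)
            _dump(report["hotspots"], out / "hotspot_summary.json")
            report["stages_run"].append(stage)

        posterior = None
        if "stvc" in config.stages:
            stage = "stvc"
            spec = config.mcmc
            spec.covariates = covariates
            spec.seed = config.seed
            state = build_stvc(panel, weights, spec)
            posterior = fit_stvc(state)
            sc, tc = extract_sc_tc(posterior)
            sc.to_csv(out / "sc.csv", index=False, float_format="%.17g")
            tc.to_csv(out / "tc.csv", index=False, float_format="%.17g")
            import pandas as pd

            vd = pd.DataFrame(
                np.column_stack(
                    [posterior.stacked("sd_mu"), posterior.stacked("sd_gamma"),
                     posterior.stacked("sd_eps")]
                ),
                columns=[f"sd_mu[{c}]" for c in covariates]
                + [f"sd_gamma[{c}]" for c in covariates]
                + ["sd_eps"],
            )
            vd.to_csv(out / "variance_draws.csv", index=False, float_format="%.17g")
            diagnostics = {
                "rhat": posterior.rhat,
                "ess": posterior.ess,
                "converged": posterior.converged,
                "include_global_coefficients": spec.include_global_coefficients,
            }
            _dump(diagnostics, out / "diagnostics.json")
            report["stvc"] = {"converged": posterior.converged}
            if not posterior.converged:
                report["warnings"].append("STVC posterior flagged non-converged")
            report["stages_run"].append(stage)

        if "stvpi" in config.stages:
            stage = "stvpi"
            if posterior is None:
                raise ValueError("stvpi stage requires the stvc stage")
            grouping = {c: panel.covariate_group[c] for c in covariates}
            result = compute_stvpi(posterior, grouping)
            result.summary.to_csv(out / "stvpi.csv", float_format="%.17g")
            ranked = rank_determinants(result, config.cumulative_threshold)
            report["stvpi"] = {
                "shares": {
                    name: dict(zip(("mean", "lo2.5", "hi97.5"), result.share(name)))
                    for name in result.summary.index
                },
                "determinants": ranked.to_dict(orient="records"),
            }
            _dump(report["stvpi"], out / "stvpi.json")
            report["stages_run"].append(stage)
    except Exception as err:
        log.removeHandler(handler)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    _dump(manifest, out / "manifest.json")
    _dump(report, out / "report.json")
    log.removeHandler(handler)
    return report
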