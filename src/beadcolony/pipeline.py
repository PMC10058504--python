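"""End-to-end pipeline: simulate → encapsulation stats → geometry → fits →
interaction map.

All randomness derives from one root seed through ``numpy.random.SeedSequence``
spawning, so an identical configuration and seed reproduce an identical output
bundle.  Each stage writes its artifact (CSV or JSON) into the output
directory and registers itself in ``manifest.json``; a stage failure halts the
run with the failing stage named while earlier artifacts are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .encapsulation import (LoadingModel, composition_fractions,
                            dominance_crossover, NoCrossoverError,
                            simulate_loading)
from .geometry import annotate_shapes
from .growth import (fit_boltzmann, fit_competition, fit_monoculture,
                     growth_curve_from_table)
from .interaction import finals_from_tables, resample_interactions
from .io import write_table
from .synthetic import ExperimentConfig, config_from_dict, generate_experiment

log = logging.getLogger("beadcolony")


@dataclass
class PipelineConfig:
    """Configuration of a full run (YAML-mirrorable)."""

    output_dir: str = "beadcolony_run"
    seed: int = 0
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    n_beads_mono: int = 200             # beads per monoculture experiment
    n_beads_sim: int = 10000            # Monte Carlo beads for loading stats
    fit_signal: str = "size"
    fit_start_h: float = 4.0
    interaction_time_h: float = 12.0
    interaction_resamples: int = 1000
    interaction_bootstrap: bool = False
    log_level: str = "INFO"


def load_pipeline_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    exp = data.pop("experiment", None)
    cfg = PipelineConfig(**data)
    if exp is not None:
        cfg.experiment = config_from_dict(exp)
    return cfg


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ("co", "mono_b", "mono_y", "loading", "fits", "interaction"),
                 np.random.SeedSequence(config.seed).spawn(6))}
    manifest = {
        "version": __version__,
        "root_seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
        "notices": [],
        "tolerances": {"ode_rtol": 1e-8, "identifiability_probe_delta": 0.02},
    }
    exp = config.experiment
    stage = "simulate"
    try:
        # -- stage 1: synthetic tables ------------------------------------
        log.info("simulating measurement tables")
        co = generate_experiment(replace(exp, seed=seeds["co"]))
        mono_b = generate_experiment(replace(
            exp, seed=seeds["mono_b"], strain_ratio=1.0,
            n_beads=config.n_beads_mono))
        mono_y = generate_experiment(replace(
            exp, seed=seeds["mono_y"], strain_ratio=0.0,
            n_beads=config.n_beads_mono))
        write_table(co, out / "co_culture.csv")
        write_table(mono_b, out / "mono_b.csv")
        write_table(mono_y, out / "mono_y.csv")
        manifest["stages"][stage] = {
            "outputs": ["co_culture.csv", "mono_b.csv", "mono_y.csv"],
            "rows": {"co": len(co), "mono_b": len(mono_b),
                     "mono_y": len(mono_y)},
        }

        # -- stage 2: encapsulation statistics ----------------------------
        stage = "encapsulation"
        model = LoadingModel(exp.mean_inoculum, exp.strain_ratio)
        frac = composition_fractions(model)
        loading = simulate_loading(model, config.n_beads_sim, seeds["loading"])
        hist, overflow = loading.joint_histogram()
        emp = loading.composition_fractions()
        report = {
            "lambda": exp.mean_inoculum, "ratio": exp.strain_ratio,
            "fractions": {"empty": frac.empty, "monoculture": frac.monoculture,
                          "coculture": frac.coculture},
            "simulated_fractions": {"empty": emp.empty,
                                    "monoculture": emp.monoculture,
                                    "coculture": emp.coculture},
            "joint_histogram_cap6": hist, "overflow_beads": overflow,
            "n_beads_simulated": config.n_beads_sim,
        }
        try:
            report["dominance_crossover_lambda"] = dominance_crossover(
                exp.strain_ratio)
        except NoCrossoverError as exc:
            report["dominance_crossover_lambda"] = None
            manifest["notices"].append(str(exc))
        _dump(report, out / "encapsulation.json")
        manifest["stages"][stage] = {"outputs": ["encapsulation.json"]}

        if len(co) == 0:
            manifest["notices"].append(
                "no colonies generated (λ = 0 or empty draw): geometry, "
                "growth and interaction stages skipped")
            for skipped in ("geometry", "fit_mono", "fit_cocult", "interaction"):
                manifest["stages"][skipped] = {"skipped": True}
            _finish(manifest, out)
            return manifest

        # -- stage 3: geometry --------------------------------------------
        stage = "geometry"
        shapes = annotate_shapes(co, bead_volume_nl=exp.bead_volume_nl,
                                 n=exp.mean_inoculum)
        shapes.to_csv(out / "shapes.csv", index=False)
        manifest["stages"][stage] = {"outputs": ["shapes.csv"]}

        # -- stage 4: growth fits -----------------------------------------
        stage = "fit_mono"
        fits = {}
        for name, table, strain in (("b", mono_b, "B"), ("y", mono_y, "Y")):
            curve = growth_curve_from_table(table, strain, config.fit_signal)
            fit = fit_monoculture(curve, fit_start=config.fit_start_h,
                                  seed=seeds["fits"])
            fits[name] = fit
            _dump({"strain": strain, "signal": config.fit_signal,
                   "params": {"r_per_h": fit.params.r,
                              "gamma": fit.params.gamma,
                              "a1_um2": fit.params.a1,
                              "a2_um2": fit.params.a2},
                   "rmse": fit.rmse, "gamma_at_bound": fit.gamma_at_bound},
                  out / f"mono_{name}.json")
        manifest["stages"][stage] = {"outputs": ["mono_b.json", "mono_y.json"]}

        stage = "fit_cocult"
        curve_b = growth_curve_from_table(co, "B", config.fit_signal,
                                          condition="co")
        curve_y = growth_curve_from_table(co, "Y", config.fit_signal,
                                          condition="co")
        # total curve: sum of the per-strain sigmoid-smoothed co-culture curves
        smooth_b = fit_boltzmann(curve_b, fit_start=config.fit_start_h,
                                 seed=seeds["fits"])
        smooth_y = fit_boltzmann(curve_y, fit_start=config.fit_start_h,
                                 seed=seeds["fits"])
        from .growth import GrowthCurve, boltzmann_eval
        t = curve_b.times
        total = GrowthCurve(t, np.asarray(boltzmann_eval(smooth_b, t))
                            + np.asarray(boltzmann_eval(smooth_y, t)))
        cfit = fit_competition(total, fits["b"].params, fits["y"].params,
                               seed=seeds["fits"])
        _dump({"c_b": cfit.params.c_b, "c_y": cfit.params.c_y,
               "rmse": cfit.rmse, "identifiable": cfit.identifiable,
               "times_h": cfit.times, "a_b_um2": cfit.a_b,
               "a_y_um2": cfit.a_y}, out / "competition.json")
        manifest["stages"][stage] = {"outputs": ["competition.json"]}

        # -- stage 5: interaction map -------------------------------------
        stage = "interaction"
        finals = finals_from_tables(mono_b, mono_y, co,
                                    time_h=config.interaction_time_h,
                                    signal=config.fit_signal)
        summary = resample_interactions(
            finals, n_resamples=config.interaction_resamples,
            seed=seeds["interaction"],
            bootstrap=config.interaction_bootstrap)
        _dump({"mean_pct": summary.mean, "se_pct": summary.se,
               "resample_sd_pct": summary.resample_sd,
               "n_pairs": summary.n_pairs,
               "n_resamples": summary.n_resamples,
               "median_b": summary.median_b, "median_y": summary.median_y},
              out / "interaction.json")
        manifest["stages"][stage] = {"outputs": ["interaction.json"]}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _finish(manifest, out)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _finish(manifest, out)
    return manifest


def _finish(manifest: dict, out: Path) -> None:
    _dump(manifest, out / "manifest.json")
    lines = [f"beadcolony {manifest['version']} run report",
             f"root seed: {manifest['root_seed']}", ""]
    for name, info in manifest["stages"].items():
        status = "SKIPPED" if info.get("skipped") else "ok"
        outputs = ", ".join(info.get("outputs", [])) or "-"
        lines.append(f"  {name:13s} {status:8s} {outputs}")
    for notice in manifest["notices"]:
        lines.append(f"  notice: {notice}")
    if "failed_stage" in manifest:
        lines.append(f"  FAILED at stage {manifest['failed_stage']}: "
                     f"{manifest['error']}")
    (out / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
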