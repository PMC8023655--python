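"""Scenario orchestration behind the command-line interface.

Each stage (simulate, synth, calibrate, gsa) reads a YAML scenario
configuration, runs the corresponding library code, writes CSV/JSON
artifacts into an output directory and records a run manifest (config
hash, seeds, stage timing, emitted files) for reproducibility.  A single
global seed fans out to per-stage seeds by stable hashing so stages are
independently reproducible.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from . import io as sp_io
from .calibrate import (CoupledForwardModel, FlowForwardModel,
                        ParameterSpace, PlantForwardModel,
                        total_log_likelihood)
from .forward import run_forward
from .hydro import TimeStepControl
from .nested import run_nested_sampling
from .params import (COLUMN_AREA_CM2, FREE_PARAMETER_NAMES,
                     default_scenario, free_parameter_bounds)
from .sensitivity import FruitAccumulationQoI, build_design, estimate_s1
from .synth import (ExperimentTemplate, NoiseModel, generate_forcing,
                    generate_observations)

__all__ = ["RunManifest", "stage_seed", "cmd_simulate", "cmd_synth",
           "cmd_calibrate", "cmd_gsa", "cmd_report"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) \
        % (2 ** 31)


@dataclass
class RunManifest:
    stage: str
    config_hash: str
    global_seed: int
    stage_seed: int
    version: str = _pkg_version
    timings_s: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, out_dir: Path) -> None:
        path = out_dir / f"manifest_{self.stage}.json"
        payload = dict(self.__dict__)
        path.write_text(json.dumps(payload, indent=2, default=str))


def _scenario_from_config(cfg: dict):
    overrides = (cfg.get("scenario") or {}).get("overrides") or {}
    return default_scenario(dict(overrides))


def _load_or_make_forcing(cfg: dict, scenario, seed: int):
    fc = cfg.get("forcing") or {}
    if fc.get("path"):
        return sp_io.read_forcing_csv(fc["path"])
    template = ExperimentTemplate()
    return generate_forcing(template, seed=seed, scenario=scenario)


def _prepare(config_path: str | Path, out_dir: str | Path, seed: int,
             stage: str):
    cfg = sp_io.load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(stage=stage,
                           config_hash=sp_io.config_hash(config_path),
                           global_seed=int(seed),
                           stage_seed=stage_seed(seed, stage))
    return cfg, out, manifest


def cmd_simulate(config_path: str | Path, out_dir: str | Path,
                 seed: int = 0) -> RunManifest:
    """Forward-simulate the configured scenario; write state CSVs and the
    mass-balance report."""
    cfg, out, manifest = _prepare(config_path, out_dir, seed, "simulate")
    t0 = time.time()
    scenario = _scenario_from_config(cfg)
    forcing = _load_or_make_forcing(cfg, scenario, manifest.stage_seed)
    n_el = int((cfg.get("scenario") or {}).get("n_elements", 100))
    result = run_forward(scenario, forcing, n_elements=n_el)
    manifest.timings_s["forward"] = round(time.time() - t0, 3)

    sp_io.write_forcing_csv(forcing, out / "forcing.csv")
    sp_io.write_flow_state_csv(result, out / "flow_state.csv", stride=10)
    sp_io.write_solute_state_csv(result, out / "solute_state.csv")
    sp_io.write_mass_balance_json(result, out / "mass_balance.json")
    tissues = {lab: result.series(lab)[1][::10].tolist()
               for lab in ("roots_CBZ", "stem_CBZ", "leaves_CBZ",
                           "fruits_CBZ", "roots_EPX", "stem_EPX",
                           "leaves_EPX", "fruits_EPX")}
    (out / "tissue_concentrations.json").write_text(
        json.dumps({"day": result.plant.t[::10].tolist(),
                    "ng_per_g_fw": tissues}, indent=2))
    manifest.outputs = ["forcing.csv", "flow_state.csv", "solute_state.csv",
                        "mass_balance.json", "tissue_concentrations.json"]
    manifest.write(out)
    return manifest


def cmd_synth(config_path: str | Path, out_dir: str | Path,
              seed: int = 0) -> RunManifest:
    """Generate a synthetic dataset bundle: forcing, noisy observations,
    and the truth record."""
    cfg, out, manifest = _prepare(config_path, out_dir, seed, "synth")
    t0 = time.time()
    scenario = _scenario_from_config(cfg)
    synth_cfg = cfg.get("synth") or {}
    noise_cfg = synth_cfg.get("noise") or {}
    noise = NoiseModel(**noise_cfg) if noise_cfg else NoiseModel()
    template = ExperimentTemplate()
    forcing = _load_or_make_forcing(cfg, scenario, manifest.stage_seed)
    obs, truth, _ = generate_observations(
        scenario, forcing, template, noise, seed=manifest.stage_seed,
        n_elements=int(synth_cfg.get("n_elements", 100)))
    manifest.timings_s["generate"] = round(time.time() - t0, 3)

    sp_io.write_forcing_csv(forcing, out / "forcing.csv")
    sp_io.write_observations_csv(obs, out / "observations.csv")
    truth_out = {"seed": truth["seed"], "noise": truth["noise"],
                 "series": {k: v.tolist()
                            for k, v in truth["series"].items()}}
    (out / "truth.json").write_text(json.dumps(truth_out, indent=2))
    manifest.outputs = ["forcing.csv", "observations.csv", "truth.json"]
    manifest.write(out)
    return manifest


def cmd_calibrate(config_path: str | Path, out_dir: str | Path,
                  seed: int = 0) -> RunManifest:
    """Nested-sampling calibration against an observation CSV."""
    cfg, out, manifest = _prepare(config_path, out_dir, seed, "calibrate")
    cal = cfg.get("calibrate") or {}
    obs_path = cal.get("observations")
    if not obs_path:
        raise ValueError("config field calibrate.observations is required")
    if not Path(obs_path).exists():
        raise FileNotFoundError(f"observation file not found: {obs_path}")
    data = sp_io.read_observations_csv(obs_path)
    names = tuple(cal.get("parameters") or FREE_PARAMETER_NAMES)
    unknown = set(names) - set(FREE_PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown calibration parameters: "
                         f"{sorted(unknown)}")
    space = ParameterSpace.subset(names)
    scenario = _scenario_from_config(cfg)
    forcing = _load_or_make_forcing(cfg, scenario, manifest.stage_seed)
    mode = cal.get("mode", "coupled")
    # reduced forward models expose only part of the observable set;
    # restrict the data to what the chosen mode can predict
    if mode == "flow":
        data = [o for o in data
                if o.extractor.startswith(("theta_", "h_"))]
    elif mode == "plant":
        tissue = ("roots_", "stem_", "leaves_", "fruits_")
        data = [o for o in data if o.extractor.startswith(tissue)]
    if not data:
        raise ValueError(f"no observation sets usable in mode {mode!r}")
    if mode == "flow":
        fwd = FlowForwardModel(space, forcing,
                               n_elements=int(cal.get("n_elements", 20)))
    elif mode == "plant":
        ref = run_forward(scenario, forcing,
                          n_elements=int(cal.get("n_elements", 50)))
        uptake = {nm: r * COLUMN_AREA_CM2
                  for nm, r in ref.solute.uptake_rate.items()}
        fwd = PlantForwardModel(space, ref.flow.t, uptake,
                                ref.flow.Ta * COLUMN_AREA_CM2,
                                t_out=ref.flow.t)
    elif mode == "coupled":
        fwd = CoupledForwardModel(space, forcing,
                                  n_elements=int(cal.get("n_elements", 50)))
    else:
        raise ValueError(f"unknown calibrate.mode: {mode!r}")

    def loglike(theta):
        return total_log_likelihood(theta, data, fwd)

    t0 = time.time()
    result = run_nested_sampling(
        loglike, space.prior_transform, space.ndim,
        n_live=int(cal.get("n_live", 300)),
        seed=manifest.stage_seed,
        dlogz=float(cal.get("dlogz", 0.05)),
        walk_steps=int(cal.get("walk_steps", 16)))
    manifest.timings_s["sampling"] = round(time.time() - t0, 3)
    sp_io.write_posterior(result, names, out)
    manifest.outputs = ["posterior_samples.csv", "posterior_summary.json"]
    manifest.write(out)
    return manifest


def cmd_gsa(config_path: str | Path, out_dir: str | Path,
            seed: int = 0) -> RunManifest:
    """RBD-FAST first-order indices of the fruit-CBZ quantity of
    interest over the calibrated parameter bounds."""
    cfg, out, manifest = _prepare(config_path, out_dir, seed, "gsa")
    gsa_cfg = cfg.get("gsa") or {}
    n = int(gsa_cfg.get("n", 1000))
    if n < 100:
        raise ValueError("gsa.n must be at least 100 for a stable "
                         "spectral estimate; increase it")
    names = tuple(gsa_cfg.get("parameters") or FREE_PARAMETER_NAMES)
    bounds_map = free_parameter_bounds()
    bounds = np.array([bounds_map[nm] for nm in names])
    scenario = _scenario_from_config(cfg)
    forcing = _load_or_make_forcing(cfg, scenario, manifest.stage_seed)
    space = ParameterSpace.subset(names)
    qoi = FruitAccumulationQoI(space, forcing,
                               n_elements=int(gsa_cfg.get("n_elements",
                                                          25)))
    t0 = time.time()
    design = build_design(n, bounds, seed=manifest.stage_seed)
    y = np.array([qoi(x) for x in design.samples])
    res = estimate_s1(y, design)
    manifest.timings_s["evaluations"] = round(time.time() - t0, 3)

    import pandas as pd
    pd.DataFrame({"factor": names, "S1": res.s1, "N": n,
                  "seed": manifest.stage_seed}) \
        .to_csv(out / "s1.csv", index=False)
    pd.DataFrame(design.samples, columns=list(names)) \
        .assign(output=y).to_csv(out / "gsa_design.csv", index=False)
    manifest.outputs = ["s1.csv", "gsa_design.csv"]
    manifest.write(out)
    return manifest


def cmd_report(out_dir: str | Path) -> dict:
    """Aggregate the manifests and key numbers found in a run directory."""
    out = Path(out_dir)
    report: dict = {"manifests": [], "summaries": {}}
    for mf in sorted(out.glob("manifest_*.json")):
        report["manifests"].append(json.loads(mf.read_text()))
    for name in ("mass_balance.json", "posterior_summary.json"):
        p = out / name
        if p.exists():
            report["summaries"][name] = json.loads(p.read_text())
    s1 = out / "s1.csv"
    if s1.exists():
        import pandas as pd
        report["summaries"]["s1.csv"] = \
            pd.read_csv(s1).to_dict(orient="records")
    return report
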