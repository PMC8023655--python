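"""Columnar-text I/O for forcing, observations, state output and configs.

All numeric artifacts are plain CSV (pandas) or JSON; configuration is
YAML whose keys mirror the model parameter symbols.  Units are declared in
column headers where they are not implied by the format.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import ObservationSet
from .forward import ForwardResult
from .hydro import Forcing
from .nested import NestedResult

__all__ = [
    "write_forcing_csv", "read_forcing_csv",
    "write_observations_csv", "read_observations_csv",
    "write_flow_state_csv", "write_solute_state_csv",
    "write_mass_balance_json",
    "write_posterior", "load_config", "config_hash",
]


def write_forcing_csv(forcing: Forcing, path: str | Path) -> None:
    df = pd.DataFrame({
        "day": forcing.t.astype(int),
        "irrigation_cm": forcing.irrigation,
        "et_cm": forcing.et,
        "lai": forcing.lai,
    })
    for nm in sorted(forcing.conc):
        df[f"conc_{nm}_mol_cm3"] = forcing.conc[nm]
    df.to_csv(path, index=False)


def read_forcing_csv(path: str | Path) -> Forcing:
    df = pd.read_csv(path)
    conc = {}
    for col in df.columns:
        if col.startswith("conc_") and col.endswith("_mol_cm3"):
            conc[col[len("conc_"):-len("_mol_cm3")]] = \
                df[col].to_numpy(float)
    return Forcing(t=df["day"].to_numpy(float),
                   irrigation=df["irrigation_cm"].to_numpy(float),
                   et=df["et_cm"].to_numpy(float),
                   lai=df["lai"].to_numpy(float),
                   conc=conc)


def write_observations_csv(observations: list[ObservationSet],
                           path: str | Path) -> None:
    rows = []
    for obs in observations:
        for t, v in zip(obs.times, obs.values):
            rows.append((obs.label, t, v, obs.sigma))
    pd.DataFrame(rows, columns=["set_label", "day", "mean", "sd"]) \
        .to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> list[ObservationSet]:
    df = pd.read_csv(path)
    out = []
    for label, grp in df.groupby("set_label", sort=False):
        out.append(ObservationSet(str(label),
                                  grp["day"].to_numpy(float),
                                  grp["mean"].to_numpy(float),
                                  float(grp["sd"].iloc[0])))
    return out


def write_flow_state_csv(result: ForwardResult, path: str | Path,
                         stride: int = 1) -> None:
    """Flow state in long format (day, depth_cm, variable, value)."""
    flow = result.flow
    t = flow.t[::stride]
    z = flow.grid.z
    frames = []
    for name, arr in (("theta", flow.theta[::stride]),
                      ("h", flow.h[::stride])):
        df = pd.DataFrame(arr, columns=np.round(-z, 4))
        df.insert(0, "day", t)
        long = df.melt(id_vars="day", var_name="depth_cm",
                       value_name="value")
        long.insert(2, "variable", name)
        frames.append(long)
    pd.concat(frames).to_csv(path, index=False)


def write_solute_state_csv(result: ForwardResult, path: str | Path,
                           stride: int = 10) -> None:
    sol = result.solute
    rho = result.scenario.medium.bulk_density
    t = sol.t[::stride]
    frames = []
    for sp in result.scenario.species:
        nm = sp.name
        for phase, arr in (("liquid", sol.conc[nm][::stride]),
                           ("sorbed", sol.sorbed[nm][::stride])):
            df = pd.DataFrame(arr, columns=np.round(-sol.z, 4))
            df.insert(0, "day", t)
            # liquid values are mol/cm^3, sorbed values mol/g
            long = df.melt(id_vars="day", var_name="depth_cm",
                           value_name="value_molar")
            long.insert(2, "species", nm)
            long.insert(3, "phase", phase)
            if phase == "liquid":
                long["value_ng_g"] = (long["value_molar"]
                                      * sp.molar_mass * 1e9 / rho)
            else:
                long["value_ng_g"] = (long["value_molar"]
                                      * sp.molar_mass * 1e9)
            frames.append(long)
    pd.concat(frames).to_csv(path, index=False)


def write_mass_balance_json(result: ForwardResult,
                            path: str | Path) -> None:
    payload = {
        "water_cm": result.flow.ledger,
        "solute_mol_per_cm2": result.solute.ledger,
        "plant_mol": result.plant.ledger,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_posterior(result: NestedResult, names: tuple[str, ...],
                    out_dir: str | Path, prefix: str = "posterior",
                    extra: dict | None = None) -> None:
    out_dir = Path(out_dir)
    df = pd.DataFrame(result.samples, columns=list(names))
    df["log_weight"] = result.log_weights
    df["log_like"] = result.log_likes
    df.to_csv(out_dir / f"{prefix}_samples.csv", index=False)
    q = result.quantiles((0.05, 0.5, 0.95))
    summary = {
        "log_evidence": result.logz,
        "log_evidence_err": result.logzerr,
        "n_calls": result.n_calls,
        "n_iterations": result.n_iter,
        "quantiles": {nm: {"q05": q[0, j], "q50": q[1, j], "q95": q[2, j]}
                      for j, nm in enumerate(names)},
    }
    if extra:
        summary.update(extra)
    (out_dir / f"{prefix}_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
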