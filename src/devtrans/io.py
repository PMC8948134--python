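"""Configuration loading, tidy-CSV writers and run manifests.

All exports are plain text: trajectories as long CSV ``time,variable,value``
with full-precision (repr round-trip) floats, loop scores as
``time,loop_id,loop_label,raw,normalized,is_dominant,net``, loop catalogs and
manifests as JSON, scenarios and models as YAML.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml

from .engine import (CausalLink, IntegrationConfig, ModelSpec, PulseSchedule,
                     TableFunction, Trajectory, VariableDef)
from .loops import Loop, LoopScoreFrame
from .scenarios import Scenario

__all__ = [
    "write_trajectory_csv", "read_trajectory_csv", "write_loop_scores_csv",
    "write_loop_catalog_json", "write_manifest", "load_scenario",
    "save_scenario", "model_to_dict", "model_from_dict", "save_model",
    "load_model",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    """Tidy long export; reading it back reproduces the series exactly."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "variable", "value"])
        for name in trajectory.values:
            series = trajectory.values[name]
            for t, v in zip(trajectory.times, series):
                w.writerow([_fmt(t), name, _fmt(v)])


def read_trajectory_csv(path, method: str = "euler") -> Trajectory:
    """Rebuild a :class:`Trajectory` from a tidy CSV written by
    :func:`write_trajectory_csv` (the integration config is inferred from the
    time grid)."""
    values: dict[str, list[float]] = {}
    times: list[float] = []
    first_var: str | None = None
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            name = row["variable"]
            if first_var is None:
                first_var = name
            if name == first_var:
                times.append(float(row["time"]))
            values.setdefault(name, []).append(float(row["value"]))
    grid = np.asarray(times)
    if len(grid) < 2:
        raise ValueError(f"trajectory in {path} has fewer than 2 time points")
    dt = float(grid[1] - grid[0])
    config = IntegrationConfig(t_start=float(grid[0]),
                               t_end=float(grid[-1]), dt=dt, method=method)
    return Trajectory(times=grid,
                      values={k: np.asarray(v) for k, v in values.items()},
                      config=config)


def write_loop_scores_csv(frame: LoopScoreFrame, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "loop_id", "loop_label", "raw", "normalized",
                    "is_dominant", "net"])
        for step, t in enumerate(frame.times):
            dom = set(frame.dominant[step])
            net = frame.net.iloc[step]
            for lp in frame.loops:
                w.writerow([
                    _fmt(t), lp.id, frame.labels.get(lp.id, lp.id),
                    _fmt(frame.raw[lp.id].iloc[step]),
                    _fmt(frame.normalized[lp.id].iloc[step]),
                    str(lp.id in dom).lower(), _fmt(net),
                ])


def write_loop_catalog_json(loops: list[Loop], path,
                            labels: dict[str, str] | None = None) -> None:
    labels = labels or {}
    entries = [{
        "id": lp.id,
        "label": labels.get(lp.id, lp.id),
        "nodes": list(lp.nodes),
        "polarity": lp.polarity,
        "rank": lp.rank,
    } for lp in loops]
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")


def write_manifest(path, payload: dict) -> None:
    """Reproducibility manifest (model version, parameters, dt, method, seed)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_scenario(path) -> Scenario:
    return Scenario.from_dict(yaml.safe_load(Path(path).read_text()))


def save_scenario(scenario: Scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=False))


# --------------------------------------------------------------------------
# ModelSpec (de)serialization

def model_to_dict(model: ModelSpec) -> dict:
    return {
        "variables": [{
            "name": v.name, "kind": v.kind, "units": v.units,
            "lower_bound": v.lower_bound, "upper_bound": v.upper_bound,
        } for v in model.variables.values()],
        "links": [[l.source, l.target, l.polarity] for l in model.links],
        "equations": dict(model.equations),
        "parameters": {k: {"value": v, "units": u}
                       for k, (v, u) in model.parameters.items()},
        "tables": {k: {"breakpoints": [list(p) for p in t.breakpoints],
                       "mode": t.mode, "units_in": t.units_in,
                       "units_out": t.units_out}
                   for k, t in model.tables.items()},
        "pulses": {k: {"times": list(s.times), "magnitude": s.magnitude,
                       "smoothing_tau": s.smoothing_tau, "units": u}
                   for k, (s, u) in model.pulses.items()},
    }


def model_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        variables={v["name"]: VariableDef(
            v["name"], v["kind"], v["units"],
            v.get("lower_bound"), v.get("upper_bound"))
            for v in d["variables"]},
        links=tuple(CausalLink(s, t, p) for s, t, p in d["links"]),
        equations=dict(d["equations"]),
        parameters={k: (p["value"], p["units"])
                    for k, p in d.get("parameters", {}).items()},
        tables={k: TableFunction(
            tuple(tuple(p) for p in t["breakpoints"]), t.get("mode", "piecewise_linear"),
            t.get("units_in", "dimensionless"), t.get("units_out", "dimensionless"))
            for k, t in d.get("tables", {}).items()},
        pulses={k: (PulseSchedule(tuple(p["times"]), p["magnitude"],
                                  p.get("smoothing_tau")), p["units"])
                for k, p in d.get("pulses", {}).items()},
    )


def save_model(model: ModelSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def load_model(path) -> ModelSpec:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))
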