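"""Scenario presets, seeded parameter sweeps, and trajectory-pattern
classification.

Six shipped presets (``case1``..``case6``) reproduce the qualitative
trajectory families the model generates: quick recovery from every school
transition; chronic escalation to the 100 ceiling; escalation triggered by
the first school transition after an initially stabilizing phase; and
tipping — recovery from the first *k* transitions followed by sustained
escalation — at different transitions.  Tipping is emergent: no equation
contains a threshold on the stock, it arises from the interacting feedback
loops (the maladaptive-behavior ratchet meeting the family-support ceiling).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .engine import IntegrationConfig, ModelError, Trajectory
from .model import CV, FS, DevTransParams, build_devtrans, simulate

__all__ = [
    "Scenario", "ClassifierConfig", "TransitionRecord", "PatternLabel",
    "UnknownScenarioError", "MissingVariableError", "ValidationError",
    "preset_scenario", "preset_names", "classify_pattern", "classify_scenario",
    "sweep_scenarios", "default_sweep_ranges", "simulate_cohort",
    "simulate_scenario",
]

PRESET_NAMES = ("case1", "case2", "case3", "case4", "case5", "case6")


class UnknownScenarioError(ModelError):
    pass


class MissingVariableError(ModelError):
    pass


class ValidationError(ModelError):
    pass


@dataclass(frozen=True)
class Scenario:
    """Named parameter set (initial conditions and pulse schedule included)."""

    name: str
    params: DevTransParams
    description: str = ""

    @property
    def initial_cv(self) -> float:
        return self.params.initial_cv

    @property
    def initial_fs(self) -> float:
        return self.params.initial_fs

    def to_dict(self) -> dict:
        return {"name": self.name, "description": self.description,
                "params": self.params.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        params = d.get("params", {})
        if "transition_times" in params:
            params = dict(params)
            params["transition_times"] = tuple(params["transition_times"])
        return cls(name=d["name"], params=DevTransParams(**params),
                   description=d.get("description", ""))


def _load_preset(name: str) -> Scenario:
    from importlib import resources
    try:
        text = resources.files("devtrans").joinpath(
            f"presets/{name}.yaml").read_text()
    except FileNotFoundError:
        raise UnknownScenarioError(f"unknown scenario {name!r}") from None
    return Scenario.from_dict(yaml.safe_load(text))


def preset_names() -> tuple[str, ...]:
    return PRESET_NAMES


def preset_scenario(name: str) -> Scenario:
    """Load one of the shipped presets ``case1``..``case6``."""
    if name not in PRESET_NAMES:
        raise UnknownScenarioError(f"unknown scenario {name!r}")
    return _load_preset(name)


def simulate_scenario(scenario: Scenario,
                      config: IntegrationConfig | None = None) -> Trajectory:
    return simulate(scenario.params, config)


# --------------------------------------------------------------------------
# trajectory-pattern classification

@dataclass(frozen=True)
class ClassifierConfig:
    """Invented, configurable classifier constants (the verbal pattern
    descriptions fix no numbers)."""

    recovery_tol: float = 5.0       # CVU; trough within this of pre-pulse = recovered
    shock_min: float = 20.0         # CVU; minimum rapid rise for a transition to count
    shock_window: float = 1.0       # years after onset within which the rise must occur
    escalation_ceiling: float = 95.0    # CVU; end-of-run level counting as chronic
    stabilizing_window: float = 1.0     # years before the first transition
    stabilizing_tol: float = 2.0    # CVU rise over the window still "stabilizing"


@dataclass(frozen=True)
class TransitionRecord:
    time: float
    pre_cv: float
    peak: float
    trough: float
    shocked: bool
    recovered: bool


@dataclass(frozen=True)
class PatternLabel:
    label: str
    evidence: tuple[TransitionRecord, ...]


def _transition_records(times, cv, transitions, horizon_end, cfg):
    recs = []
    active = sorted(t for t in transitions if times[0] <= t < horizon_end)
    boundaries = active[1:] + [horizon_end]
    for onset, nxt in zip(active, boundaries):
        i_on = int(np.searchsorted(times, onset - 1e-9))
        i_nxt = int(np.searchsorted(times, nxt - 1e-9))
        pre = float(cv[i_on])
        window = cv[i_on + 1:i_nxt + 1]
        if len(window) == 0:
            continue
        peak = float(window.max())
        trough = float(window.min())
        i_sw = int(np.searchsorted(times, onset + cfg.shock_window + 1e-9))
        early_peak = float(cv[i_on + 1:max(i_on + 2, min(i_sw, i_nxt) + 1)].max())
        shocked = early_peak >= pre + cfg.shock_min
        recovered = shocked and trough <= pre + cfg.recovery_tol
        recs.append(TransitionRecord(onset, pre, peak, trough, shocked, recovered))
    return recs


def classify_pattern(trajectory: Trajectory,
                     transitions: tuple[float, ...] | None = None,
                     rules: ClassifierConfig | None = None) -> PatternLabel:
    """Assign exactly one qualitative label to a trajectory.

    Per transition, *recovered* means the trough before the next transition
    returns to within ``recovery_tol`` of the pre-pulse level; a transition
    must first register a net shock of at least ``shock_min`` (near the
    ceiling a clipped pulse produces no real shock).  The labels:

    - ``recovery``: every transition shocked and recovered;
    - ``tipping_after_k``: transitions 1..k recovered, none afterwards;
    - ``chronic_escalation``: no recovery and the series ends at or above the
      escalation ceiling, having been rising already before the first
      transition;
    - ``post_transition_escalation``: as chronic, but the series was
      stabilizing (flat or falling) just before the first transition;
    - ``stabilizing``: anything else.
    """
    cfg = rules or ClassifierConfig()
    if CV not in trajectory.values:
        raise MissingVariableError(f"trajectory lacks the {CV} series")
    cv = np.asarray(trajectory.values[CV], dtype=float)
    times = np.asarray(trajectory.times, dtype=float)
    if transitions is None:
        transitions = (5.0, 11.0, 14.0, 18.0)
    recs = _transition_records(times, cv, transitions, times[-1], cfg)

    recovered = [r.recovered for r in recs]
    end_cv = float(cv[-1])

    if recs and any(recovered):
        if all(recovered):
            return PatternLabel("recovery", tuple(recs))
        k = 0
        while k < len(recovered) and recovered[k]:
            k += 1
        if k >= 1 and not any(recovered[k:]):
            return PatternLabel(f"tipping_after_{k}", tuple(recs))
        return PatternLabel("stabilizing", tuple(recs))
    if end_cv >= cfg.escalation_ceiling:
        if recs:
            t1 = recs[0].time
            i1 = int(np.searchsorted(times, t1 - 1e-9))
            i0 = int(np.searchsorted(times, t1 - cfg.stabilizing_window - 1e-9))
            i0 = max(0, min(i0, i1))
            rise = float(cv[i1] - cv[i0])
            if recs[0].shocked and rise <= cfg.stabilizing_tol:
                return PatternLabel("post_transition_escalation", tuple(recs))
        return PatternLabel("chronic_escalation", tuple(recs))
    return PatternLabel("stabilizing", tuple(recs))


def classify_scenario(scenario: Scenario,
                      config: IntegrationConfig | None = None,
                      rules: ClassifierConfig | None = None) -> PatternLabel:
    traj = simulate_scenario(scenario, config)
    return classify_pattern(traj, scenario.params.transition_times, rules)


# --------------------------------------------------------------------------
# seeded sweeps and cohorts

#: admissible range of each sweepable numeric parameter
ADMISSIBLE = {
    "initial_cv": (0.0, 100.0), "initial_fs": (0.0, 100.0),
    "cv_at": (0.05, 20.0), "fs_at": (0.05, 20.0),
    "family_response_delay": (0.05, 10.0), "onset_mb_delay": (0.05, 10.0),
    "ac_per_cv": (0.0, 2.0), "mb_per_ac": (0.0, 2.0),
    "effect_mb_gain": (0.0, 3.0), "effect_fs_gain": (0.0, 3.0),
    "fr_mb_weight": (0.0, 3.0), "fr_ac_weight": (0.0, 3.0),
    "transition_magnitude": (0.0, 100.0),
}


def default_sweep_ranges(base: DevTransParams | None = None,
                         rel: float = 0.5) -> dict[str, tuple[float, float]]:
    """±``rel`` (default 50%) ranges around a base parameter set, clipped to
    the admissible bounds."""
    base = base or preset_scenario("case1").params
    ranges = {}
    for name, (lo_adm, hi_adm) in ADMISSIBLE.items():
        x = getattr(base, name)
        lo, hi = x * (1 - rel), x * (1 + rel)
        ranges[name] = (max(lo, lo_adm), min(max(hi, lo), hi_adm))
    return ranges


def sweep_scenarios(ranges: dict[str, tuple[float, float]], n: int,
                    seed: int, base: DevTransParams | None = None) -> list[Scenario]:
    """Draw ``n`` scenarios with parameters sampled uniformly and
    independently from ``ranges`` (deterministic given the seed)."""
    if n < 1:
        raise ValidationError("sweep size n must be >= 1")
    base = base or preset_scenario("case1").params
    for name, (lo, hi) in ranges.items():
        if name not in ADMISSIBLE:
            raise ValidationError(f"unknown sweep parameter {name!r}")
        lo_adm, hi_adm = ADMISSIBLE[name]
        if lo > hi:
            raise ValidationError(f"{name}: low {lo} exceeds high {hi}")
        if lo < lo_adm or hi > hi_adm:
            raise ValidationError(
                f"{name}: range ({lo}, {hi}) outside admissible "
                f"({lo_adm}, {hi_adm})")
    rng = np.random.default_rng(seed)
    names = sorted(ranges)
    scenarios = []
    for i in range(n):
        draw = {name: float(rng.uniform(*ranges[name])) for name in names}
        scenarios.append(Scenario(
            name=f"sweep-{i:04d}",
            params=base.replace(**draw),
            description=f"uniform draw {i} (seed {seed})",
        ))
    return scenarios


def simulate_cohort(scenarios: list[Scenario],
                    config: IntegrationConfig | None = None,
                    include_loops: bool = True,
                    rules: ClassifierConfig | None = None) -> pd.DataFrame:
    """Simulate and classify each scenario; long tidy table with one row per
    scenario and grid point (columns: scenario, time, cv, fs, label,
    dominant)."""
    from .loops import dominance_profile
    config = config or IntegrationConfig()
    frames = []
    for sc in scenarios:
        traj = simulate_scenario(sc, config)
        label = classify_pattern(traj, sc.params.transition_times, rules)
        dom: list[str]
        if include_loops:
            model = build_devtrans(sc.params)
            prof = dominance_profile(traj, model)
            dom = ["|".join(d) for d in prof.dominant]
        else:
            dom = [""] * len(traj.times)
        frames.append(pd.DataFrame({
            "scenario": sc.name,
            "time": traj.times,
            "cv": traj.values[CV],
            "fs": traj.values[FS],
            "label": label.label,
            "dominant": dom,
        }))
    return pd.concat(frames, ignore_index=True)
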