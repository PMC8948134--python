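"""The developmental-transitions model of cognitive vulnerabilities (CV) and
family support (FS).

Two stocks on a 0-100 scale — ``CognitiveVulnerabilities`` (CVU) and
``FamilySupport`` (FSU) — interact through three major feedback mechanisms:

* **R1** (reinforcing): CV raises avoidant coping, which after an onset delay
  raises maladaptive behaviors, whose effect feeds the developmental inflow
  to CV — a vicious (or, in reverse, virtuous) cycle.
* **B1** (balancing): the family perceives maladaptive behaviors after a
  response delay, mobilizes support, and the support effect drains CV.
* **B2** (balancing): the same mechanism responding to perceived avoidant
  coping directly.

School transitions at ages 5, 11, 14 and 18 hit CV with pulse shocks of 50
units.  Headroom ``(max_cv - CV)/max_cv`` on the inflow and ``CV/max_cv`` on
the drain realize the minor stock-flow loops that keep the stock inside its
0-100 range structurally.  All effects route through monotone table
functions, linear (identity) by default.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .engine import (CausalLink, IncompleteValuationError, IntegrationConfig,
                     InvalidParameterError, ModelSpec, PulseSchedule,
                     TableFunction, VariableDef, integrate)

__all__ = [
    "DevTransParams", "default_params", "build_devtrans", "initial_state",
    "devtrans_rates", "simulate", "MAJOR_LOOP_NODES", "label_major_loops",
    "CV", "FS", "MB", "PMB", "PAC",
]

# canonical variable names
CV = "CognitiveVulnerabilities"
FS = "FamilySupport"
MB = "MaladaptiveBehaviors"
PMB = "PerceivedMB"
PAC = "PerceivedAC"
AC = "AvoidantCoping"
FR_MB = "FamilyResponseToMB"
FR_AC = "FamilyResponseToAC"
IFS = "IndicatedFamilySupport"
EFF_MB = "EffectOfMBonCV"
EFF_FS = "EffectOfFSonCV"
DEV_CV = "DevelopmentalChangeInCV"
DRAIN_CV = "SupportDrainOfCV"
SHOCK = "TransitionShock"
PULSE_IN = "TransitionPulse"
PENDING = "PendingTransitionShock"

# identity effect tables sampled every 10 units, so the continuously
# differentiable (smoothstep) variant stays a small perturbation of linear
_IDENTITY = tuple((10.0 * i, 10.0 * i) for i in range(11))


@dataclass(frozen=True)
class DevTransParams:
    """Parameters and initial conditions for one simulated individual.

    Times are in years; gains carry the provisional psychological units
    (CVU, ACU, MBU, FSU) of the 0-100 ratio scales.
    """

    initial_cv: float = 10.0          # CVU, 0-100
    initial_fs: float = 25.0          # FSU, 0-100
    max_cv: float = 100.0             # CVU ceiling
    max_fs: float = 100.0             # FSU ceiling
    cv_at: float = 0.75               # years; CV adjustment time (both effects)
    fs_at: float = 0.75               # years; family-support adjustment time
    family_response_delay: float = 0.5    # years; perception delay (MB and AC)
    onset_mb_delay: float = 2.0       # years; avoidant coping -> maladaptive behaviors
    ac_per_cv: float = 1.0            # ACU per CVU
    mb_per_ac: float = 1.0            # MBU per ACU
    effect_mb_gain: float = 0.5       # CVU per MBU
    effect_fs_gain: float = 0.9       # CVU per FSU
    fr_mb_weight: float = 1.0         # FSU per MBU
    fr_ac_weight: float = 1.0         # FSU per ACU
    transition_times: tuple[float, ...] = (5.0, 11.0, 14.0, 18.0)
    transition_magnitude: float = 50.0    # CVU per pulse
    pulse_smoothing_tau: float | None = None   # years; None = discrete pulse
    table_mode: str = "piecewise_linear"

    def __post_init__(self):
        object.__setattr__(self, "transition_times",
                           tuple(float(t) for t in self.transition_times))
        problems = self.validate()
        if problems:
            raise InvalidParameterError("; ".join(problems))

    def validate(self) -> list[str]:
        p: list[str] = []
        for name in ("cv_at", "fs_at", "family_response_delay", "onset_mb_delay"):
            if getattr(self, name) <= 0:
                p.append(f"{name} must be > 0")
        for name in ("ac_per_cv", "mb_per_ac", "effect_mb_gain", "effect_fs_gain",
                     "fr_mb_weight", "fr_ac_weight"):
            if getattr(self, name) < 0:
                p.append(f"{name} must be >= 0")
        for name in ("initial_cv", "initial_fs", "transition_magnitude"):
            if not 0 <= getattr(self, name) <= 100:
                p.append(f"{name} must lie in [0, 100]")
        if self.max_cv <= 0 or self.max_fs <= 0:
            p.append("max_cv and max_fs must be > 0")
        if any(not 0 <= t <= 21 for t in self.transition_times):
            p.append("transition_times must lie within [0, 21]")
        if self.pulse_smoothing_tau is not None and self.pulse_smoothing_tau <= 0:
            p.append("pulse_smoothing_tau must be > 0 when set")
        if self.table_mode not in ("piecewise_linear", "smooth_algebraic"):
            p.append(f"unknown table_mode {self.table_mode!r}")
        return p

    def replace(self, **kw) -> "DevTransParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transition_times"] = list(self.transition_times)
        return d


def default_params() -> DevTransParams:
    """Documented defaults: transitions at ages 5/11/14/18 with magnitude 50
    on the 0-100 scale, horizon 0-21 years; remaining constants are the
    recovery (case1) preset values."""
    return DevTransParams()


def build_devtrans(params: DevTransParams) -> ModelSpec:
    """Assemble the :class:`ModelSpec` for one parameterization."""
    mode = params.table_mode
    tables = {
        "table_ac": TableFunction(_IDENTITY, mode, "CVU", "CVU"),
        "table_mb": TableFunction(_IDENTITY, mode, "ACU", "ACU"),
        "table_emb": TableFunction(_IDENTITY, mode, "MBU", "MBU"),
        "table_efs": TableFunction(_IDENTITY, mode, "FSU", "FSU"),
    }
    schedule = PulseSchedule(params.transition_times, params.transition_magnitude,
                             params.pulse_smoothing_tau)
    smoothed = params.pulse_smoothing_tau is not None

    variables = {
        CV: VariableDef(CV, "stock", "CVU", 0.0, params.max_cv),
        FS: VariableDef(FS, "stock", "FSU", 0.0, params.max_fs),
        MB: VariableDef(MB, "smooth_state", "MBU", 0.0, 100.0),
        PMB: VariableDef(PMB, "smooth_state", "MBU", 0.0, 100.0),
        PAC: VariableDef(PAC, "smooth_state", "ACU", 0.0, 100.0),
        AC: VariableDef(AC, "auxiliary", "ACU"),
        FR_MB: VariableDef(FR_MB, "auxiliary", "FSU"),
        FR_AC: VariableDef(FR_AC, "auxiliary", "FSU"),
        IFS: VariableDef(IFS, "auxiliary", "FSU"),
        EFF_MB: VariableDef(EFF_MB, "auxiliary", "CVU"),
        EFF_FS: VariableDef(EFF_FS, "auxiliary", "CVU"),
        DEV_CV: VariableDef(DEV_CV, "flow", "CVU/year"),
        DRAIN_CV: VariableDef(DRAIN_CV, "flow", "CVU/year"),
        "ChangeInFS": VariableDef("ChangeInFS", "flow", "FSU/year"),
        SHOCK: VariableDef(SHOCK, "flow", "CVU/year"),
    }
    equations = {
        AC: "ac_per_cv * table_ac(CognitiveVulnerabilities)",
        MB: "(mb_per_ac * table_mb(AvoidantCoping) - MaladaptiveBehaviors)"
            " / onset_mb_delay",
        PMB: "(MaladaptiveBehaviors - PerceivedMB) / family_response_delay",
        PAC: "(AvoidantCoping - PerceivedAC) / family_response_delay",
        FR_MB: "fr_mb_weight * PerceivedMB",
        FR_AC: "fr_ac_weight * PerceivedAC",
        IFS: "min(FamilyResponseToMB + FamilyResponseToAC, max_fs)",
        "ChangeInFS": "(IndicatedFamilySupport - FamilySupport) / fs_at",
        EFF_MB: "effect_mb_gain * table_emb(MaladaptiveBehaviors)",
        EFF_FS: "effect_fs_gain * table_efs(FamilySupport)",
        DEV_CV: "EffectOfMBonCV * (max_cv - CognitiveVulnerabilities) / max_cv"
                " / cv_at",
        DRAIN_CV: "EffectOfFSonCV * (CognitiveVulnerabilities / max_cv) / cv_at",
        CV: "DevelopmentalChangeInCV + TransitionShock - SupportDrainOfCV",
        FS: "ChangeInFS",
    }
    links = [
        CausalLink(CV, AC, 1),
        CausalLink(AC, MB, 1), CausalLink(MB, MB, -1),
        CausalLink(MB, PMB, 1), CausalLink(PMB, PMB, -1),
        CausalLink(AC, PAC, 1), CausalLink(PAC, PAC, -1),
        CausalLink(PMB, FR_MB, 1),
        CausalLink(PAC, FR_AC, 1),
        CausalLink(FR_MB, IFS, 1), CausalLink(FR_AC, IFS, 1),
        CausalLink(IFS, "ChangeInFS", 1), CausalLink(FS, "ChangeInFS", -1),
        CausalLink("ChangeInFS", FS, 1),
        CausalLink(MB, EFF_MB, 1),
        CausalLink(FS, EFF_FS, 1),
        CausalLink(EFF_MB, DEV_CV, 1), CausalLink(CV, DEV_CV, -1),
        CausalLink(EFF_FS, DRAIN_CV, 1), CausalLink(CV, DRAIN_CV, 1),
        CausalLink(DEV_CV, CV, 1), CausalLink(SHOCK, CV, 1),
        CausalLink(DRAIN_CV, CV, -1),
    ]
    if smoothed:
        # first-order material delay: pending mass drains into the shock flow
        variables[PENDING] = VariableDef(PENDING, "stock", "CVU")
        variables[PULSE_IN] = VariableDef(PULSE_IN, "flow", "CVU/year")
        equations[PULSE_IN] = "pulse_transitions(t)"
        equations[SHOCK] = "PendingTransitionShock / pulse_smoothing_tau"
        equations[PENDING] = "TransitionPulse - TransitionShock"
        links += [
            CausalLink(PULSE_IN, PENDING, 1),
            CausalLink(SHOCK, PENDING, -1),
            CausalLink(PENDING, SHOCK, 1),
        ]
    else:
        equations[SHOCK] = "pulse_transitions(t)"

    parameters = {
        "max_cv": (params.max_cv, "CVU"),
        "max_fs": (params.max_fs, "FSU"),
        "cv_at": (params.cv_at, "year"),
        "fs_at": (params.fs_at, "year"),
        "family_response_delay": (params.family_response_delay, "year"),
        "onset_mb_delay": (params.onset_mb_delay, "year"),
        "ac_per_cv": (params.ac_per_cv, "ACU/CVU"),
        "mb_per_ac": (params.mb_per_ac, "MBU/ACU"),
        "effect_mb_gain": (params.effect_mb_gain, "CVU/MBU"),
        "effect_fs_gain": (params.effect_fs_gain, "CVU/FSU"),
        "fr_mb_weight": (params.fr_mb_weight, "FSU/MBU"),
        "fr_ac_weight": (params.fr_ac_weight, "FSU/ACU"),
    }
    if smoothed:
        parameters["pulse_smoothing_tau"] = (params.pulse_smoothing_tau, "year")

    return ModelSpec(
        variables=variables,
        links=tuple(links),
        equations=equations,
        parameters=parameters,
        tables=tables,
        pulses={"pulse_transitions": (schedule, "CVU/year")},
    )


def initial_state(params: DevTransParams) -> dict:
    """Initial values for all states; smooth states start in equilibrium with
    their inputs (no spurious startup transient)."""
    from .engine import table_eval
    model_tables = {
        "table_ac": TableFunction(_IDENTITY, params.table_mode, "CVU", "CVU"),
        "table_mb": TableFunction(_IDENTITY, params.table_mode, "ACU", "ACU"),
    }
    ac0 = params.ac_per_cv * table_eval(model_tables["table_ac"], params.initial_cv)
    mb0 = params.mb_per_ac * table_eval(model_tables["table_mb"], ac0)
    state = {CV: params.initial_cv, FS: params.initial_fs,
             MB: mb0, PMB: mb0, PAC: ac0}
    if params.pulse_smoothing_tau is not None:
        state[PENDING] = 0.0
    return state


def simulate(params: DevTransParams,
             config: IntegrationConfig | None = None):
    """Build the model and integrate it; convenience wrapper."""
    config = config or IntegrationConfig()
    model = build_devtrans(params)
    return integrate(model, initial_state(params), config)


def devtrans_rates(valuation: dict, params: DevTransParams) -> dict:
    """Closed-form state derivatives computed directly from the model
    equations, bypassing the generic engine (an independent oracle for
    testing :func:`devtrans.engine.integrate`).

    ``valuation`` must carry the five states plus ``TransitionShock``.
    Only the default linear tables are supported here.
    """
    if params.table_mode != "piecewise_linear":
        raise InvalidParameterError("oracle rates support linear tables only")
    needed = (CV, FS, MB, PMB, PAC, SHOCK)
    missing = [k for k in needed if k not in valuation]
    if missing:
        raise IncompleteValuationError(f"valuation missing {missing}")
    cv, fs = valuation[CV], valuation[FS]
    mb, pmb, pac = valuation[MB], valuation[PMB], valuation[PAC]

    def interp(x):  # identity table with endpoint clamping
        return float(np.interp(x, [0.0, 100.0], [0.0, 100.0]))

    ac = params.ac_per_cv * interp(cv)
    eff_mb = params.effect_mb_gain * interp(mb)
    eff_fs = params.effect_fs_gain * interp(fs)
    indicated = min(params.fr_mb_weight * pmb + params.fr_ac_weight * pac,
                    params.max_fs)
    dcv = (eff_mb * (params.max_cv - cv) / params.max_cv / params.cv_at
           + valuation[SHOCK]
           - eff_fs * (cv / params.max_cv) / params.cv_at)
    return {
        CV: dcv,
        FS: (indicated - fs) / params.fs_at,
        MB: (params.mb_per_ac * interp(ac) - mb) / params.onset_mb_delay,
        PMB: (mb - pmb) / params.family_response_delay,
        PAC: (ac - pac) / params.family_response_delay,
    }


#: node sets of the three named major loops (used to attach R1/B1/B2 labels)
MAJOR_LOOP_NODES = {
    "R1": frozenset({CV, AC, MB, EFF_MB, DEV_CV}),
    "B1": frozenset({CV, AC, MB, PMB, FR_MB, IFS, "ChangeInFS", FS, EFF_FS,
                     DRAIN_CV}),
    "B2": frozenset({CV, AC, PAC, FR_AC, IFS, "ChangeInFS", FS, EFF_FS,
                     DRAIN_CV}),
}


def label_major_loops(loops) -> dict[str, str]:
    """Map loop ids to R1/B1/B2 labels (minor loops get ``minor:<nodes>``)."""
    labels = {}
    for loop in loops:
        nodes = frozenset(loop.nodes)
        for name, ref in MAJOR_LOOP_NODES.items():
            if nodes == ref:
                labels[loop.id] = name
                break
        else:
            labels[loop.id] = "minor:" + "/".join(loop.nodes)
    return labels
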