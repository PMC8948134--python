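import numpy as np
import pytest

from devtrans import (IntegrationConfig, build_devtrans, dominance_profile,
                      preset_scenario, simulate)
from devtrans.engine import (CausalLink, ModelSpec, Trajectory, VariableDef,
                             integrate)


@pytest.fixture(scope="session")
def case1():
    return preset_scenario("case1")


@pytest.fixture(scope="session")
def case1_model(case1):
    return build_devtrans(case1.params)


@pytest.fixture(scope="session")
def case1_traj(case1):
    return simulate(case1.params, IntegrationConfig())


@pytest.fixture(scope="session")
def case1_profile(case1_traj, case1_model):
    return dominance_profile(case1_traj, case1_model)


@pytest.fixture(scope="session")
def preset_runs():
    """Simulated trajectory per preset at default settings."""
    out = {}
    for name in ("case1", "case2", "case3", "case4", "case5", "case6"):
        sc = preset_scenario(name)
        out[name] = (sc, simulate(sc.params, IntegrationConfig()))
    return out


def make_decay_model(tau=2.0):
    """Single-stock goal-seeking test system dS/dt = -S/tau."""
    return ModelSpec(
        variables={
            "S": VariableDef("S", "stock", "U"),
            "Outflow": VariableDef("Outflow", "flow", "U/year"),
        },
        links=(CausalLink("S", "Outflow", 1), CausalLink("Outflow", "S", -1)),
        equations={"S": "-Outflow", "Outflow": "S / tau"},
        parameters={"tau": (tau, "year")},
    )


def make_growth_model(g=0.5):
    """Single-loop exponential growth dS/dt = g*S."""
    return ModelSpec(
        variables={
            "S": VariableDef("S", "stock", "U"),
            "Inflow": VariableDef("Inflow", "flow", "U/year"),
        },
        links=(CausalLink("S", "Inflow", 1), CausalLink("Inflow", "S", 1)),
        equations={"S": "Inflow", "Inflow": "g * S"},
        parameters={"g": (g, "1/year")},
    )


def make_goalseek_model(goal=100.0, tau=2.0):
    """Single-loop goal seeking dS/dt = (G - S)/tau."""
    return ModelSpec(
        variables={
            "S": VariableDef("S", "stock", "U"),
            "Adjust": VariableDef("Adjust", "flow", "U/year"),
        },
        links=(CausalLink("S", "Adjust", -1), CausalLink("Adjust", "S", 1)),
        equations={"S": "Adjust", "Adjust": "(G - S) / tau"},
        parameters={"G": (goal, "U"), "tau": (tau, "year")},
    )


def make_algebra_model():
    """Two independent stocks feeding auxiliaries Z = X + Y and W = 10 - X,
    used to exercise link-score attribution directly."""
    return ModelSpec(
        variables={
            "X": VariableDef("X", "stock", "U"),
            "Y": VariableDef("Y", "stock", "U"),
            "FX": VariableDef("FX", "flow", "U/year"),
            "FY": VariableDef("FY", "flow", "U/year"),
            "Z": VariableDef("Z", "auxiliary", "U"),
            "W": VariableDef("W", "auxiliary", "U"),
        },
        links=(
            CausalLink("FX", "X", 1), CausalLink("FY", "Y", 1),
            CausalLink("X", "Z", 1), CausalLink("Y", "Z", 1),
            CausalLink("X", "W", -1),
        ),
        equations={"X": "FX", "Y": "FY", "FX": "0.0", "FY": "0.0",
                   "Z": "X + Y", "W": "10.0 - X"},
        parameters={},
    )


def hand_trajectory(model, columns, dt=1.0):
    """Build a Trajectory directly from per-variable value lists."""
    n = len(next(iter(columns.values())))
    config = IntegrationConfig(t_start=0.0, t_end=dt * (n - 1), dt=dt)
    return Trajectory(
        times=config.grid(),
        values={k: np.asarray(v, dtype=float) for k, v in columns.items()},
        config=config,
    )
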