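import math

import numpy as np
import pytest

from devtrans.engine import (AlignmentError, CausalLink, IncompleteValuationError,
                             IntegrationConfig, InvalidParameterError,
                             InvalidTableError, ModelSpec, ModelStructureError,
                             NumericFailureError, PulseSchedule, TableFunction,
                             VariableDef, check_units, eval_auxiliaries,
                             integrate, pulse_value, smooth_rate, table_eval)

from conftest import make_decay_model


# -- table functions --------------------------------------------------------

IDENTITY = TableFunction(((0, 0), (100, 100)))


@pytest.mark.parametrize("table, x, expected", [
    (IDENTITY, 37.0, 37.0),                 # linear identity
    (IDENTITY, 150.0, 100.0),               # clamp above
    (IDENTITY, -5.0, 0.0),                  # clamp below
    (TableFunction(((0, 0), (50, 10), (100, 40))), 75.0, 25.0),  # hand interp
])
def test_table_piecewise_linear(table, x, expected):
    assert table_eval(table, x) == pytest.approx(expected)


def test_table_smooth_variant_interpolates_and_stays_monotone():
    t = TableFunction(((0, 0), (50, 10), (100, 40)), mode="smooth_algebraic")
    for x, y in t.breakpoints:
        assert table_eval(t, x) == pytest.approx(y)
    xs = np.linspace(-10, 110, 400)
    ys = [table_eval(t, x) for x in xs]
    assert all(b >= a - 1e-12 for a, b in zip(ys, ys[1:]))
    assert table_eval(t, 200.0) == 40.0


@pytest.mark.parametrize("bad", [
    dict(breakpoints=((0, 0),)),                          # too few points
    dict(breakpoints=((0, 0), (0, 1))),                   # x not increasing
    dict(breakpoints=((0, 0), (1, 5), (2, 3))),           # y not monotone
    dict(breakpoints=((0, 0), (1, 1)), mode="spline"),    # unknown mode
])
def test_table_validation(bad):
    with pytest.raises(InvalidTableError):
        TableFunction(**bad)


# -- smooth rate ------------------------------------------------------------

def test_smooth_rate_arithmetic_and_equilibrium():
    assert smooth_rate(0.0, 100.0, 2.0) == pytest.approx(50.0)
    assert smooth_rate(42.0, 42.0, 3.0) == 0.0
    with pytest.raises(InvalidParameterError):
        smooth_rate(0.0, 1.0, 0.0)


def _smooth_step_model(tau=2.0):
    return ModelSpec(
        variables={"P": VariableDef("P", "smooth_state", "U")},
        links=(CausalLink("P", "P", -1),),
        equations={"P": "(target - P) / tau"},
        parameters={"target": (100.0, "U"), "tau": (tau, "year")},
    )


def test_smooth_step_response_converges_to_closed_form():
    """Simulated first-order response to a step approaches 1 - e^{-t/tau};
    the max error halves when dt halves (first-order convergence)."""
    model = _smooth_step_model(tau=2.0)
    errors = {}
    for dt in (1 / 16, 1 / 32, 1 / 64):
        traj = integrate(model, {"P": 0.0}, IntegrationConfig(0, 4, dt))
        exact = 100.0 * (1.0 - np.exp(-traj.times / 2.0))
        errors[dt] = float(np.abs(traj["P"] - exact).max())
    assert abs(100.0 * (1 - math.e ** -1) - 63.212) < 1e-3  # anchor at t=tau
    assert errors[1 / 32] < errors[1 / 16]
    assert errors[1 / 16] / errors[1 / 32] == pytest.approx(2.0, rel=0.2)
    assert errors[1 / 32] / errors[1 / 64] == pytest.approx(2.0, rel=0.2)


# -- pulse schedules --------------------------------------------------------

SCHEDULE = PulseSchedule((5.0, 11.0, 14.0, 18.0), 50.0)


def test_pulse_rate_at_onset_and_between():
    assert pulse_value(SCHEDULE, 5.0, 0.25) == pytest.approx(200.0)
    assert pulse_value(SCHEDULE, 6.0, 0.25) == 0.0
    with pytest.raises(AlignmentError):
        pulse_value(SCHEDULE, 5.1, 0.25)


def test_pulse_validation():
    with pytest.raises(InvalidParameterError):
        PulseSchedule((5.0,), -1.0)
    with pytest.raises(InvalidParameterError):
        PulseSchedule((5.0,), 50.0, smoothing_tau=0.0)


def _accumulator_with_pulse(smoothing_tau=None):
    """Pure accumulator stock fed only by the pulse train (optionally routed
    through a first-order material delay)."""
    variables = {
        "S": VariableDef("S", "stock", "U"),
        "Shock": VariableDef("Shock", "flow", "U/year"),
    }
    if smoothing_tau is None:
        equations = {"S": "Shock", "Shock": "pulse_p(t)"}
        links = (CausalLink("Shock", "S", 1),)
        return ModelSpec(variables, links, equations, {},
                         pulses={"pulse_p": (PulseSchedule((5.0,), 50.0), "U/year")})
    variables["Pending"] = VariableDef("Pending", "stock", "U")
    variables["Inject"] = VariableDef("Inject", "flow", "U/year")
    equations = {
        "S": "Shock", "Inject": "pulse_p(t)",
        "Shock": "Pending / tau", "Pending": "Inject - Shock",
    }
    links = (CausalLink("Shock", "S", 1), CausalLink("Inject", "Pending", 1),
             CausalLink("Shock", "Pending", -1), CausalLink("Pending", "Shock", 1))
    return ModelSpec(variables, links, equations, {"tau": (smoothing_tau, "year")},
                     pulses={"pulse_p": (PulseSchedule((5.0,), 50.0, smoothing_tau),
                                         "U/year")})


def test_pulse_mass_conserved_discrete():
    model = _accumulator_with_pulse()
    traj = integrate(model, {"S": 0.0}, IntegrationConfig(0, 21, 1 / 32))
    assert traj["S"][-1] == pytest.approx(50.0, abs=1e-9)


def test_pulse_mass_conserved_through_material_delay():
    model = _accumulator_with_pulse(smoothing_tau=0.5)
    traj = integrate(model, {"S": 0.0, "Pending": 0.0},
                     IntegrationConfig(0, 21, 1 / 32))
    # integral of the delayed response over [5, 21] carries the full mass
    assert traj["S"][-1] == pytest.approx(50.0, rel=0.01)
    assert traj["S"][5 * 32 - 1] == 0.0


def test_pulse_onset_must_align_to_grid():
    model = _accumulator_with_pulse()
    with pytest.raises(AlignmentError):
        integrate(model, {"S": 0.0}, IntegrationConfig(0, 21, 0.75))


# -- evaluation and integration --------------------------------------------

def test_eval_auxiliaries_complete_and_validated():
    model = make_decay_model()
    val = eval_auxiliaries(model, {"S": 10.0}, 0.0)
    assert set(val) == {"S", "Outflow"}
    assert val["Outflow"] == pytest.approx(5.0)
    with pytest.raises(IncompleteValuationError):
        eval_auxiliaries(model, {}, 0.0)


def test_decay_matches_closed_form():
    model = make_decay_model(tau=2.0)
    traj = integrate(model, {"S": 100.0}, IntegrationConfig(0, 2, 1 / 32))
    assert traj["S"][-1] == pytest.approx(100.0 * math.exp(-1.0), abs=0.5)


def test_integration_is_deterministic():
    model = make_decay_model()
    a = integrate(model, {"S": 100.0}, IntegrationConfig(0, 4, 1 / 32))
    b = integrate(model, {"S": 100.0}, IntegrationConfig(0, 4, 1 / 32))
    assert np.array_equal(a["S"], b["S"])
    assert np.array_equal(a["Outflow"], b["Outflow"])


def test_rk4_much_more_accurate_than_euler():
    model = make_decay_model(tau=2.0)
    cfg = IntegrationConfig(0, 2, 1 / 8, method="rk4")
    traj = integrate(model, {"S": 100.0}, cfg)
    assert traj["S"][-1] == pytest.approx(100.0 * math.exp(-1.0), abs=1e-4)


def test_clipping_enforces_bounds_and_is_logged():
    model = ModelSpec(
        variables={"S": VariableDef("S", "stock", "U", 0.0, 10.0),
                   "F": VariableDef("F", "flow", "U/year")},
        links=(CausalLink("F", "S", 1),),
        equations={"S": "F", "F": "5.0"},
        parameters={},
    )
    traj = integrate(model, {"S": 0.0}, IntegrationConfig(0, 4, 1 / 4))
    assert traj["S"].max() == 10.0
    assert traj.clip_events and traj.clip_events[0][1] == "S"


def test_nonfinite_value_names_variable_and_time():
    model = ModelSpec(
        variables={"S": VariableDef("S", "stock", "U"),
                   "F": VariableDef("F", "flow", "U/year")},
        links=(CausalLink("S", "F", 1), CausalLink("F", "S", 1)),
        equations={"S": "F", "F": "S * S * 1e150"},
        parameters={},
    )
    with pytest.raises(NumericFailureError, match="S"):
        integrate(model, {"S": 1e200}, IntegrationConfig(0, 1, 1 / 4))


def test_integration_config_validation():
    with pytest.raises(InvalidParameterError):
        IntegrationConfig(0, 0, 1 / 32)
    with pytest.raises(InvalidParameterError):
        IntegrationConfig(0, 1, 0.3)       # not an integer number of steps
    with pytest.raises(InvalidParameterError):
        IntegrationConfig(0, 1, 1 / 8, method="heun")


# -- model structure validation ---------------------------------------------

def test_link_set_must_match_equation_dependencies():
    with pytest.raises(ModelStructureError, match="disagrees"):
        ModelSpec(
            variables={"S": VariableDef("S", "stock", "U"),
                       "F": VariableDef("F", "flow", "U/year")},
            links=(CausalLink("F", "S", 1), CausalLink("S", "S", 1)),
            equations={"S": "F", "F": "2.0"},
            parameters={},
        )


def test_auxiliary_cycles_rejected_at_build_time():
    with pytest.raises(ModelStructureError, match="cycle"):
        ModelSpec(
            variables={"A": VariableDef("A", "auxiliary", "U"),
                       "B": VariableDef("B", "auxiliary", "U")},
            links=(CausalLink("A", "B", 1), CausalLink("B", "A", 1)),
            equations={"A": "B", "B": "A"},
            parameters={},
        )


def test_stock_equation_must_be_signed_flow_sum():
    with pytest.raises(ModelStructureError):
        ModelSpec(
            variables={"S": VariableDef("S", "stock", "U"),
                       "F": VariableDef("F", "flow", "U/year")},
            links=(CausalLink("F", "S", 1),),
            equations={"S": "2.0 * F", "F": "1.0"},
            parameters={},
        )


# -- dimensional consistency -------------------------------------------------

def test_check_units_flags_flow_without_per_year():
    model = ModelSpec(
        variables={"S": VariableDef("S", "stock", "CVU"),
                   "F": VariableDef("F", "flow", "CVU")},
        links=(CausalLink("F", "S", 1),),
        equations={"S": "F", "F": "k"},
        parameters={"k": (1.0, "CVU")},
    )
    report = check_units(model)
    assert len(report) == 1 and "S" in report[0]


def test_check_units_accepts_smooth_rate_form():
    model = _smooth_step_model()
    assert check_units(model) == []
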