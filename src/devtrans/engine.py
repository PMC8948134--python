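"""Generic continuous-time stock-and-flow simulation core.

A :class:`ModelSpec` declares variables (stocks, flows, auxiliaries,
parameters and first-order smooth states), signed causal links, and one
evaluable equation per non-parameter variable.  :func:`integrate` solves the
resulting ODE system on a fixed grid with Euler or classic RK4 stepping,
supporting monotone table functions, pulse trains, post-step clipping to
declared stock bounds, and dimensional-consistency checking.

Conventions follow standard system-dynamics practice: stock equations are
signed sums of flow variables (units stock/year), smooth-state equations are
rate expressions ``(input - state)/tau``, and table inputs outside the
breakpoint range clamp to the nearest endpoint.
"""
from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field

import numpy as np

from .units import DIMENSIONLESS, YEAR, Unit, UnitSyntaxError, parse_units

__all__ = [
    "ModelError", "InvalidTableError", "InvalidParameterError", "ModelStructureError",
    "AlignmentError", "NumericFailureError", "IncompleteValuationError",
    "VariableDef", "CausalLink", "TableFunction", "PulseSchedule",
    "IntegrationConfig", "ModelSpec", "Trajectory",
    "table_eval", "smooth_rate", "pulse_value", "eval_auxiliaries", "integrate",
    "check_units",
]

KINDS = ("stock", "flow", "auxiliary", "parameter", "smooth_state")
STATE_KINDS = ("stock", "smooth_state")

#: functions available inside equations, besides table and pulse calls
_EQ_FUNCS = {
    "min": min, "max": max, "abs": abs,
    "exp": math.exp, "log": math.log, "sqrt": math.sqrt, "tanh": math.tanh,
}


class ModelError(Exception):
    """Base class for model-definition and simulation errors."""


class InvalidTableError(ModelError):
    pass


class InvalidParameterError(ModelError):
    pass


class ModelStructureError(ModelError):
    pass


class AlignmentError(ModelError):
    """A time does not fall on the integration grid."""


class NumericFailureError(ModelError):
    """A non-finite value appeared during integration."""


class IncompleteValuationError(ModelError):
    pass


@dataclass(frozen=True)
class VariableDef:
    name: str
    kind: str
    units: str
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ModelStructureError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if (self.lower_bound is None) != (self.upper_bound is None):
            raise ModelStructureError(
                f"{self.name!r}: bounds must be given together or not at all")
        if self.lower_bound is not None and self.lower_bound >= self.upper_bound:
            raise ModelStructureError(f"{self.name!r}: lower_bound >= upper_bound")
        parse_units(self.units)  # raises UnitSyntaxError early

    @property
    def unit(self) -> Unit:
        return parse_units(self.units)


@dataclass(frozen=True)
class CausalLink:
    source: str
    target: str
    polarity: int

    def __post_init__(self):
        if self.polarity not in (1, -1):
            raise ModelStructureError(
                f"link {self.source}->{self.target}: polarity must be +1 or -1")


@dataclass(frozen=True)
class TableFunction:
    """Monotone lookup relating one variable to another.

    ``piecewise_linear`` interpolates linearly between breakpoints;
    ``smooth_algebraic`` uses a per-segment cubic Hermite smoothstep, which is
    continuously differentiable everywhere (slope zero at each breakpoint and
    at the clamped ends) and interpolates the same breakpoints.  Inputs
    outside the x-range clamp to the nearest endpoint's y.
    """

    breakpoints: tuple[tuple[float, float], ...]
    mode: str = "piecewise_linear"
    units_in: str = "dimensionless"
    units_out: str = "dimensionless"

    def __post_init__(self):
        pts = tuple((float(x), float(y)) for x, y in self.breakpoints)
        object.__setattr__(self, "breakpoints", pts)
        if len(pts) < 2:
            raise InvalidTableError("table needs at least 2 breakpoints")
        xs = [x for x, _ in pts]
        ys = [y for _, y in pts]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise InvalidTableError("table x values must be strictly increasing")
        nondec = all(b >= a for a, b in zip(ys, ys[1:]))
        noninc = all(b <= a for a, b in zip(ys, ys[1:]))
        if not (nondec or noninc):
            raise InvalidTableError("table y values must be monotone")
        if self.mode not in ("piecewise_linear", "smooth_algebraic"):
            raise InvalidTableError(f"unknown table mode {self.mode!r}")

    def __call__(self, x: float) -> float:
        return table_eval(self, x)


def table_eval(table: TableFunction, x: float) -> float:
    """Evaluate ``table`` at ``x`` with endpoint clamping."""
    pts = table.breakpoints
    if x <= pts[0][0]:
        return pts[0][1]
    if x >= pts[-1][0]:
        return pts[-1][1]
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if x0 <= x <= x1:
            u = (x - x0) / (x1 - x0)
            if table.mode == "smooth_algebraic":
                u = u * u * (3.0 - 2.0 * u)
            return y0 + (y1 - y0) * u
    raise AssertionError("unreachable")  # pragma: no cover


def smooth_rate(state: float, input: float, tau: float) -> float:
    """Rate of a first-order information delay: ``(input - state)/tau``."""
    if tau <= 0:
        raise InvalidParameterError(f"smooth time constant must be > 0, got {tau}")
    return (input - state) / tau


@dataclass(frozen=True)
class PulseSchedule:
    """Train of discrete shocks: ``magnitude`` stock units added per onset.

    With ``smoothing_tau`` set, model builders route the discrete pulse
    through a first-order material delay (pending-mass stock draining at
    ``pending/tau``), which distributes the same total mass over time.
    """

    times: tuple[float, ...]
    magnitude: float
    smoothing_tau: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if self.magnitude < 0:
            raise InvalidParameterError("pulse magnitude must be >= 0")
        if self.smoothing_tau is not None and self.smoothing_tau <= 0:
            raise InvalidParameterError("pulse smoothing_tau must be > 0 when present")


def pulse_value(schedule: PulseSchedule, t: float, dt: float) -> float:
    """Discrete pulse rate at grid time ``t``: ``magnitude/dt`` for the single
    step beginning at each onset, else 0, so each pulse integrates to exactly
    ``magnitude``."""
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    k = t / dt
    if abs(k - round(k)) > 1e-6:
        raise AlignmentError(f"t={t} is not on the integration grid (dt={dt})")
    rate = 0.0
    for onset in schedule.times:
        if abs(t - onset) <= dt * 1e-6:
            rate += schedule.magnitude / dt
    return rate


@dataclass(frozen=True)
class IntegrationConfig:
    t_start: float = 0.0
    t_end: float = 21.0
    dt: float = 1.0 / 32.0
    method: str = "euler"

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise InvalidParameterError("t_end must exceed t_start")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        n = (self.t_end - self.t_start) / self.dt
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError("(t_end - t_start)/dt must be an integer")
        if self.method not in ("euler", "rk4"):
            raise InvalidParameterError(f"unknown method {self.method!r}")

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt))

    def grid(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_steps + 1)


# --------------------------------------------------------------------------
# equation parsing

def _parse_equation(name: str, expr: str, varnames, paramnames, tablenames, pulsenames):
    """Compile one equation; return (code, variable deps, pulse calls)."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as e:
        raise ModelStructureError(f"equation for {name!r} does not parse: {e}") from e
    deps: set[str] = set()
    pulses: set[str] = set()
    for node in ast.walk(tree):
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name):
                raise ModelStructureError(f"{name!r}: only simple calls allowed")
            fn = node.func.id
            if fn not in _EQ_FUNCS and fn not in tablenames and fn not in pulsenames:
                raise ModelStructureError(f"{name!r}: unknown function {fn!r}")
            if fn in pulsenames:
                pulses.add(fn)
        elif isinstance(node, ast.Name) and not isinstance(node.ctx, ast.Load):
            raise ModelStructureError(f"{name!r}: assignment not allowed in equations")
        elif isinstance(node, ast.Attribute):
            raise ModelStructureError(f"{name!r}: attribute access not allowed")
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            ident = node.id
            if ident in varnames:
                deps.add(ident)
            elif ident in paramnames or ident == "t" or ident in _EQ_FUNCS \
                    or ident in tablenames or ident in pulsenames:
                pass
            else:
                raise ModelStructureError(f"{name!r}: unknown identifier {ident!r}")
    code = compile(tree, f"<equation:{name}>", "eval")
    return code, deps, pulses, tree


def _stock_flow_signs(name: str, tree: ast.Expression) -> dict[str, int]:
    """A stock equation must be a +/- sum of flow names; return flow -> sign."""
    signs: dict[str, int] = {}

    def walk(node, sign):
        if isinstance(node, ast.BinOp) and isinstance(node.op, (ast.Add, ast.Sub)):
            walk(node.left, sign)
            walk(node.right, sign if isinstance(node.op, ast.Add) else -sign)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            walk(node.operand, -sign)
        elif isinstance(node, ast.Name):
            if node.id in signs:
                raise ModelStructureError(f"stock {name!r}: flow {node.id!r} appears twice")
            signs[node.id] = sign
        else:
            raise ModelStructureError(
                f"stock {name!r}: equation must be a signed sum of flow names")

    walk(tree.body, 1)
    if not signs:
        raise ModelStructureError(f"stock {name!r} has no flows")
    return signs


@dataclass
class ModelSpec:
    """Declarative model: variables, links, equations, parameters.

    Validated and compiled on construction; raises :class:`ModelStructureError`
    when equation dependencies disagree with the declared link set, when
    auxiliaries form a cycle, or when a stock equation is not a signed sum of
    flows.
    """

    variables: dict[str, VariableDef]
    links: tuple[CausalLink, ...]
    equations: dict[str, str]
    parameters: dict[str, tuple[float, str]]
    tables: dict[str, TableFunction] = field(default_factory=dict)
    pulses: dict[str, tuple[PulseSchedule, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.links = tuple(self.links)
        names = list(self.variables)
        if len(set(names)) != len(names):
            raise ModelStructureError("duplicate variable names")
        overlap = set(names) & (set(self.parameters) | set(self.tables) | set(self.pulses))
        if overlap:
            raise ModelStructureError(f"names declared twice: {sorted(overlap)}")
        for v in self.variables.values():
            if v.kind == "parameter":
                raise ModelStructureError(
                    f"{v.name!r}: declare parameters in .parameters, not .variables")
        for pname, (value, units) in self.parameters.items():
            parse_units(units)
        varnames = set(names)
        self._code: dict[str, object] = {}
        self._deps: dict[str, set[str]] = {}
        self._trees: dict[str, ast.Expression] = {}
        self._stock_signs: dict[str, dict[str, int]] = {}
        self.impulse_flows: set[str] = set()
        for name, vdef in self.variables.items():
            if name not in self.equations:
                raise ModelStructureError(f"no equation for {name!r}")
            code, deps, pulses, tree = _parse_equation(
                name, self.equations[name], varnames, set(self.parameters),
                set(self.tables), set(self.pulses))
            if pulses:
                if vdef.kind != "flow" or not isinstance(tree.body, ast.Call):
                    raise ModelStructureError(
                        f"{name!r}: pulse calls may only form the entire equation of a flow")
                self.impulse_flows.add(name)
            self._code[name] = code
            self._deps[name] = deps
            self._trees[name] = tree
            if vdef.kind == "stock":
                signs = _stock_flow_signs(name, tree)
                for fname in signs:
                    if self.variables.get(fname, None) is None or \
                            self.variables[fname].kind != "flow":
                        raise ModelStructureError(
                            f"stock {name!r}: {fname!r} is not a declared flow")
                self._stock_signs[name] = signs
        extra = set(self.equations) - varnames
        if extra:
            raise ModelStructureError(f"equations for undeclared variables: {sorted(extra)}")
        self._check_links()
        self._toposort()
        self._base_ns = dict(_EQ_FUNCS)
        self._base_ns.update({k: v for k, (v, _) in self.parameters.items()})
        self._base_ns.update(self.tables)

    # -- structural validation ------------------------------------------------

    def _check_links(self):
        declared: dict[tuple[str, str], int] = {}
        for l in self.links:
            for end in (l.source, l.target):
                if end not in self.variables:
                    raise ModelStructureError(f"link references unknown variable {end!r}")
            if (l.source, l.target) in declared:
                raise ModelStructureError(f"duplicate link {l.source}->{l.target}")
            declared[(l.source, l.target)] = l.polarity
        expected: dict[tuple[str, str], int | None] = {}
        for name, deps in self._deps.items():
            if self.variables[name].kind == "stock":
                for fname, sign in self._stock_signs[name].items():
                    expected[(fname, name)] = sign
            else:
                for d in deps:
                    expected[(d, name)] = None  # polarity declared, not derived
        if set(declared) != set(expected):
            missing = set(expected) - set(declared)
            spurious = set(declared) - set(expected)
            raise ModelStructureError(
                f"link set disagrees with equation dependencies; "
                f"missing={sorted(missing)} spurious={sorted(spurious)}")
        for key, sign in expected.items():
            if sign is not None and declared[key] != sign:
                raise ModelStructureError(
                    f"integration link {key[0]}->{key[1]}: declared polarity "
                    f"{declared[key]} but equation sign {sign}")

    def _toposort(self):
        algebraic = [n for n, v in self.variables.items()
                     if v.kind in ("auxiliary", "flow")]
        alg = set(algebraic)
        indeg = {n: 0 for n in algebraic}
        out: dict[str, list[str]] = {n: [] for n in algebraic}
        for n in algebraic:
            for d in self._deps[n]:
                if d in alg:
                    indeg[n] += 1
                    out[d].append(n)
        order, ready = [], sorted(n for n, k in indeg.items() if k == 0)
        while ready:
            n = ready.pop(0)
            order.append(n)
            for m in sorted(out[n]):
                indeg[m] -= 1
                if indeg[m] == 0:
                    ready.append(m)
        if len(order) != len(algebraic):
            cyc = sorted(n for n in algebraic if n not in order)
            raise ModelStructureError(f"cycle among auxiliaries/flows: {cyc}")
        self._order = order

    # -- evaluation -----------------------------------------------------------

    @property
    def state_names(self) -> list[str]:
        return [n for n, v in self.variables.items() if v.kind in STATE_KINDS]

    def link(self, source: str, target: str) -> CausalLink:
        for l in self.links:
            if l.source == source and l.target == target:
                return l
        raise ModelStructureError(f"unknown link {source}->{target}")

    def _pulse_ns(self, dt: float | None, zero: bool = False) -> dict:
        ns = {}
        for name, (schedule, _units) in self.pulses.items():
            if zero:
                ns[name] = lambda t: 0.0
            else:
                if dt is None:
                    raise InvalidParameterError(
                        "dt required to evaluate a model with pulse schedules")
                ns[name] = (lambda sched: lambda t: pulse_value(sched, t, dt))(schedule)
        return ns

    def eval_single(self, name: str, values: dict, t: float = 0.0,
                    dt: float | None = None, zero_pulses: bool = False) -> float:
        """Evaluate one variable's equation against an explicit valuation."""
        ns = dict(self._base_ns)
        ns.update(self._pulse_ns(dt, zero=zero_pulses))
        ns.update(values)
        ns["t"] = t
        return float(eval(self._code[name], {"__builtins__": {}}, ns))


def eval_auxiliaries(model: ModelSpec, stock_values: dict, t: float,
                     dt: float | None = None, zero_pulses: bool = False) -> dict:
    """Complete valuation of every model variable given the state values.

    Auxiliaries and flows are evaluated in topological order; the result holds
    exactly one entry per declared variable (state levels included, state
    rates excluded).
    """
    missing = [s for s in model.state_names if s not in stock_values]
    if missing:
        raise IncompleteValuationError(f"missing state values for {missing}")
    val = {s: float(stock_values[s]) for s in model.state_names}
    ns = dict(model._base_ns)
    ns.update(model._pulse_ns(dt, zero=zero_pulses))
    ns.update(val)
    ns["t"] = t
    for name in model._order:
        v = float(eval(model._code[name], {"__builtins__": {}}, ns))
        ns[name] = v
        val[name] = v
    return val


@dataclass
class Trajectory:
    """Simulated series for every model variable on the time grid.

    Flow values at index ``i`` are the rates applied over step ``i -> i+1``
    (exact for Euler; instantaneous start-of-step evaluations for RK4).
    """

    times: np.ndarray
    values: dict[str, np.ndarray]
    config: IntegrationConfig
    clip_events: list[tuple[float, str]] = field(default_factory=list)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def to_frame(self):
        import pandas as pd
        frames = [
            pd.DataFrame({"time": self.times, "variable": name, "value": series})
            for name, series in self.values.items()
        ]
        return pd.concat(frames, ignore_index=True)


def _state_rates(model: ModelSpec, states: dict, t: float, dt: float,
                 zero_pulses: bool = False) -> tuple[dict, dict]:
    val = eval_auxiliaries(model, states, t, dt, zero_pulses=zero_pulses)
    rates = {}
    for s in model.state_names:
        if model.variables[s].kind == "stock":
            r = 0.0
            for fname, sign in model._stock_signs[s].items():
                r += sign * val[fname]
            rates[s] = r
        else:
            rates[s] = model.eval_single(s, val, t, dt, zero_pulses=zero_pulses)
    return rates, val


def integrate(model: ModelSpec, initials: dict, config: IntegrationConfig) -> Trajectory:
    """Integrate the model over the configured grid.

    Euler: ``S(t+dt) = clip(S(t) + dt*netflow)``.  RK4 uses the classic
    four-stage scheme on the continuous part, with discrete pulse mass added
    once per step (at the onset step) so the integrated shock per pulse is
    exactly the schedule magnitude for both methods.  Clipping to declared
    bounds is applied after the combined step and logged on the trajectory.
    """
    missing = [s for s in model.state_names if s not in initials]
    if missing:
        raise IncompleteValuationError(f"initials missing for states {missing}")
    for schedule, _units in model.pulses.values():
        for onset in schedule.times:
            k = (onset - config.t_start) / config.dt
            if abs(k - round(k)) > 1e-6:
                raise AlignmentError(
                    f"pulse onset {onset} does not align to the grid (dt={config.dt})")

    dt = config.dt
    n = config.n_steps
    times = config.grid()
    series = {name: np.empty(n + 1) for name in model.variables}
    clip_events: list[tuple[float, str]] = []
    states = {s: float(initials[s]) for s in model.state_names}

    def record(i, val):
        for name, x in val.items():
            series[name][i] = x

    for i in range(n):
        t = times[i]
        if config.method == "euler":
            rates, val = _state_rates(model, states, t, dt)
            record(i, val)
            pulsing = any(val[f] != 0.0 for f in model.impulse_flows)
            if pulsing:
                # left-point impulse: mass lands first, continuous rates
                # then act on the boosted state for the rest of the step
                base = dict(states)
                for s, signs in model._stock_signs.items():
                    for fname, sign in signs.items():
                        if fname in model.impulse_flows:
                            base[s] += sign * dt * val[fname]
                            v = model.variables[s]
                            if v.lower_bound is not None and not \
                                    v.lower_bound <= base[s] <= v.upper_bound:
                                clip_events.append((float(t), s))
                                base[s] = min(max(base[s], v.lower_bound),
                                              v.upper_bound)
                rates, _ = _state_rates(model, base, t, dt, zero_pulses=True)
                new = {s: base[s] + dt * rates[s] for s in base}
            else:
                new = {s: states[s] + dt * rates[s] for s in states}
        else:  # rk4: impulse mass lands at the step start, then staged dynamics
            _, val_full = _state_rates(model, states, t, dt)
            record(i, val_full)
            base = dict(states)
            for s, signs in model._stock_signs.items():
                for fname, sign in signs.items():
                    if fname in model.impulse_flows:
                        base[s] += sign * dt * val_full[fname]
                        v = model.variables[s]
                        if v.lower_bound is not None and not \
                                v.lower_bound <= base[s] <= v.upper_bound:
                            clip_events.append((float(t), s))
                            base[s] = min(max(base[s], v.lower_bound),
                                          v.upper_bound)
            k1, _ = _state_rates(model, base, t, dt, zero_pulses=True)
            mid = {s: base[s] + 0.5 * dt * k1[s] for s in base}
            k2, _ = _state_rates(model, mid, t + 0.5 * dt, dt, zero_pulses=True)
            mid = {s: base[s] + 0.5 * dt * k2[s] for s in base}
            k3, _ = _state_rates(model, mid, t + 0.5 * dt, dt, zero_pulses=True)
            end = {s: base[s] + dt * k3[s] for s in base}
            k4, _ = _state_rates(model, end, t + dt, dt, zero_pulses=True)
            new = {}
            for s in base:
                step = dt * (k1[s] + 2 * k2[s] + 2 * k3[s] + k4[s]) / 6.0
                new[s] = base[s] + step
        for s, x in new.items():
            if not math.isfinite(x):
                raise NumericFailureError(
                    f"non-finite value for {s!r} at t={times[i + 1]:g}")
            v = model.variables[s]
            if v.lower_bound is not None:
                if x < v.lower_bound or x > v.upper_bound:
                    clip_events.append((float(times[i + 1]), s))
                    x = min(max(x, v.lower_bound), v.upper_bound)
            new[s] = x
        states = new

    _, val = _state_rates(model, states, times[n], dt)
    record(n, val)
    return Trajectory(times=times, values=series, config=config,
                      clip_events=clip_events)


# --------------------------------------------------------------------------
# dimensional consistency

def _derive_units(model: ModelSpec, node: ast.AST, violations: list[str],
                  ctx: str) -> Unit:
    if isinstance(node, ast.Expression):
        return _derive_units(model, node.body, violations, ctx)
    if isinstance(node, ast.Constant):
        return DIMENSIONLESS
    if isinstance(node, ast.Name):
        if node.id == "t":
            return YEAR
        if node.id in model.variables:
            return model.variables[node.id].unit
        if node.id in model.parameters:
            return parse_units(model.parameters[node.id][1])
        return DIMENSIONLESS
    if isinstance(node, ast.UnaryOp):
        return _derive_units(model, node.operand, violations, ctx)
    if isinstance(node, ast.BinOp):
        left = _derive_units(model, node.left, violations, ctx)
        right = _derive_units(model, node.right, violations, ctx)
        if isinstance(node.op, (ast.Add, ast.Sub)):
            if left != right:
                violations.append(
                    f"{ctx}: adding incompatible units {left} and {right}")
            return left
        if isinstance(node.op, ast.Mult):
            return left * right
        if isinstance(node.op, ast.Div):
            return left / right
        if isinstance(node.op, ast.Pow):
            if isinstance(node.right, ast.Constant) and \
                    float(node.right.value) == int(node.right.value):
                return left ** int(node.right.value)
            violations.append(f"{ctx}: non-integer exponent on unitful quantity")
            return DIMENSIONLESS
        violations.append(f"{ctx}: unsupported operator for unit derivation")
        return DIMENSIONLESS
    if isinstance(node, ast.Call):
        fn = node.func.id
        args = [_derive_units(model, a, violations, ctx) for a in node.args]
        if fn in model.tables:
            tab = model.tables[fn]
            if args and args[0] != parse_units(tab.units_in):
                violations.append(
                    f"{ctx}: table {fn} expects input {tab.units_in}, got {args[0]}")
            return parse_units(tab.units_out)
        if fn in model.pulses:
            return parse_units(model.pulses[fn][1])
        if fn in ("min", "max", "abs"):
            for u in args[1:]:
                if u != args[0]:
                    violations.append(f"{ctx}: {fn}() arguments have mixed units")
            return args[0]
        # transcendental functions require dimensionless arguments
        for u in args:
            if not u.is_dimensionless:
                violations.append(f"{ctx}: {fn}() argument must be dimensionless")
        return DIMENSIONLESS
    violations.append(f"{ctx}: unsupported expression for unit derivation")
    return DIMENSIONLESS


def check_units(model: ModelSpec) -> list[str]:
    """Dimensional-consistency report; an empty list means consistent.

    Every equation's derived right-hand-side units must equal the declared
    units of the variable (for stocks and smooth states: declared units per
    year, since their equations are rates)."""
    violations: list[str] = []
    for name, vdef in model.variables.items():
        derived = _derive_units(model, model._trees[name], violations, name)
        declared = vdef.unit
        if vdef.kind in STATE_KINDS:
            declared = declared / YEAR
        if derived != declared:
            violations.append(
                f"{name}: derived units {derived} != expected {declared}")
    return violations
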