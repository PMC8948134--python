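"""Feedback-loop enumeration and loop-dominance scoring.

Implements the link-score / loop-score method for attributing a system's
per-step behavior to its feedback loops:

* the **link score** of ``x -> z`` at a step is the signed proportion of
  ``z``'s change attributable to ``x``'s change, holding the other inputs of
  ``z`` at their previous values (exact ceteris-paribus re-evaluation of
  ``z``'s equation);
* the **loop score** is the product of link scores around a simple directed
  cycle;
* scores are **normalized** so absolute values sum to 100%, on a -100..100
  scale where positive means reinforcing-acting and negative
  balancing-acting;
* the **net score** (sum of normalized scores) tells whether reinforcing or
  balancing mechanisms drive the current trend, and the **dominant set** is
  the smallest group of loops whose cumulative absolute score reaches the
  threshold (default 50%).

Integration links (flow ``f`` -> stock ``S``) attribute ``dt*f`` of the
stock's net change to the flow, signed by the flow's structural sign in the
stock equation.  Links into a smooth state factor into a rate re-evaluation
score times a rate-to-state integration score, equivalent to modelling the
smooth with an explicit flow.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .engine import ModelError, ModelSpec, Trajectory

__all__ = [
    "Loop", "LoopScoreFrame", "InvalidThresholdError", "UnknownLinkError",
    "enumerate_loops", "link_score", "loop_scores", "normalize_scores",
    "net_loop_score", "dominant_loops", "dominance_profile",
    "dominance_shift_sequence", "major_loop_sequence",
]

EPS = 1e-12   # stationarity guard for zero-change denominators


class InvalidThresholdError(ModelError):
    pass


class UnknownLinkError(ModelError):
    pass


@dataclass(frozen=True)
class Loop:
    """A simple directed cycle through the model's causal graph."""

    id: str
    nodes: tuple[str, ...]          # canonical rotation (starts at min node)
    links: tuple                    # CausalLink cycle, nodes[i] -> nodes[i+1]
    polarity: str                   # "reinforcing" | "balancing"
    rank: str                       # "major" | "minor"

    def __len__(self):
        return len(self.links)


def _canonical(cycle: list[str]) -> tuple[str, ...]:
    i = cycle.index(min(cycle))
    return tuple(cycle[i:] + cycle[:i])


def enumerate_loops(model: ModelSpec) -> list[Loop]:
    """Every simple directed cycle of the computational graph, classified by
    polarity (sign of the product of link polarities) and rank (minor iff the
    cycle spans at most two distinct nodes: the structural stock-flow and
    smooth-state self cycles).  Deterministic ordering."""
    g = nx.DiGraph()
    g.add_nodes_from(model.variables)
    for l in model.links:
        g.add_edge(l.source, l.target)
    loops = []
    for cycle in nx.simple_cycles(g):
        nodes = _canonical(list(cycle))
        ring = nodes + (nodes[0],)
        links = tuple(model.link(a, b) for a, b in zip(ring, ring[1:]))
        sign = 1
        for l in links:
            sign *= l.polarity
        loops.append(Loop(
            id="L" + hashlib.sha1("→".join(nodes).encode()).hexdigest()[:8],
            nodes=nodes,
            links=links,
            polarity="reinforcing" if sign > 0 else "balancing",
            rank="minor" if len(set(nodes)) <= 2 else "major",
        ))
    loops.sort(key=lambda lp: (tuple(sorted(lp.nodes)), lp.nodes))
    return loops


def _aux_score(model, values_prev, values_now, name, source, t_prev, dt, eps):
    """Ceteris-paribus score of source -> name for an algebraic equation."""
    z_prev, z_now = values_prev[name], values_now[name]
    x_prev, x_now = values_prev[source], values_now[source]
    dz, dx = z_now - z_prev, x_now - x_prev
    if abs(dz) < eps or abs(dx) < eps:
        return 0.0
    mixed = dict(values_prev)
    mixed[source] = x_now
    z_mixed = model.eval_single(name, mixed, t_prev, dt)
    dxz = z_mixed - z_prev
    if abs(dxz) < eps:
        return 0.0
    return math.copysign(abs(dxz) / abs(dz), dxz * dx)


def link_score(trajectory: Trajectory, model: ModelSpec, link, step: int,
               eps: float = EPS) -> float:
    """Signed link score of ``link`` over the step ending at index ``step``."""
    if step < 1:
        raise ModelError("link scores need step >= 1")
    if link not in model.links:
        raise UnknownLinkError(f"link {link.source}->{link.target} not in model")
    dt = trajectory.config.dt
    times = trajectory.times
    vals = trajectory.values
    prev = {k: float(v[step - 1]) for k, v in vals.items()}
    now = {k: float(v[step]) for k, v in vals.items()}
    return _link_score_from_rows(model, prev, now, link, times[step - 1], dt, eps)


def _link_score_from_rows(model, prev, now, link, t_prev, dt, eps):
    target = link.target
    kind = model.variables[target].kind
    if kind in ("auxiliary", "flow"):
        return _aux_score(model, prev, now, target, link.source, t_prev, dt, eps)
    if kind == "stock":
        ds = now[target] - prev[target]
        contrib = dt * prev[link.source]
        if abs(ds) < eps or abs(contrib) < eps:
            return 0.0
        return link.polarity * abs(contrib) / abs(ds)
    # smooth state: rate re-evaluation x rate->state integration factor
    dz = now[target] - prev[target]
    if abs(dz) < eps:
        return 0.0
    r_prev = model.eval_single(target, prev, t_prev, dt)
    r_now = model.eval_single(target, now, t_prev + dt, dt)
    dr = r_now - r_prev
    dx = now[link.source] - prev[link.source]
    if abs(dr) < eps or abs(dx) < eps or abs(dt * r_prev) < eps:
        return 0.0
    mixed = dict(prev)
    mixed[link.source] = now[link.source]
    r_mixed = model.eval_single(target, mixed, t_prev, dt)
    dxr = r_mixed - r_prev
    if abs(dxr) < eps:
        return 0.0
    rate_score = math.copysign(abs(dxr) / abs(dr), dxr * dx)
    return rate_score * abs(dt * r_prev) / abs(dz)


def _all_link_scores(trajectory, model, links, eps=EPS) -> dict:
    """Per-link score series over all steps (index 0 is defined as 0)."""
    n = len(trajectory.times)
    dt = trajectory.config.dt
    vals = trajectory.values
    out = {l: np.zeros(n) for l in links}
    prev = {k: float(v[0]) for k, v in vals.items()}
    for i in range(1, n):
        now = {k: float(v[i]) for k, v in vals.items()}
        t_prev = trajectory.times[i - 1]
        for l in links:
            out[l][i] = _link_score_from_rows(model, prev, now, l, t_prev, dt, eps)
        prev = now
    return out


def loop_scores(trajectory: Trajectory, model: ModelSpec,
                loops: list[Loop], eps: float = EPS) -> pd.DataFrame:
    """Raw loop-score series: product of link scores at each step."""
    links = sorted({l for lp in loops for l in lp.links},
                   key=lambda l: (l.source, l.target))
    per_link = _all_link_scores(trajectory, model, links, eps)
    data = {}
    for lp in loops:
        prod = np.ones(len(trajectory.times))
        for l in lp.links:
            prod = prod * per_link[l]
        data[lp.id] = prod
    return pd.DataFrame(data, index=pd.Index(trajectory.times, name="time"))


def normalize_scores(raw) -> np.ndarray:
    """Scale one step's raw scores so absolute values sum to 100; all-zero raw
    scores stay zero (a declared stationary instant)."""
    raw = np.asarray(raw, dtype=float)
    denom = np.abs(raw).sum()
    if denom < EPS:
        return np.zeros_like(raw)
    return 100.0 * raw / denom


def net_loop_score(frame: "LoopScoreFrame", step: int) -> float:
    """Sum of normalized scores at ``step``: > 0 reinforcing-driven,
    < 0 balancing-driven, 0 dynamic equilibrium."""
    return float(frame.normalized.iloc[step].sum())


def dominant_loops(frame: "LoopScoreFrame", step: int,
                   threshold: float = 50.0) -> tuple[str, ...]:
    """Shortest prefix of loops, ranked by |normalized| (ties by id), whose
    cumulative absolute score reaches ``threshold``; empty at stationary
    instants."""
    if not 0 < threshold <= 100:
        raise InvalidThresholdError(f"threshold must lie in (0, 100], got {threshold}")
    row = frame.normalized.iloc[step]
    return _dominant_from_row(row, threshold)


def _dominant_from_row(row: pd.Series, threshold: float) -> tuple[str, ...]:
    order = sorted(row.index, key=lambda i: (-abs(row[i]), i))
    picked, cum = [], 0.0
    for lid in order:
        if abs(row[lid]) < EPS:
            break
        picked.append(lid)
        cum += abs(row[lid])
        if cum >= threshold - 1e-9:
            return tuple(picked)
    return ()


@dataclass
class LoopScoreFrame:
    """Per-loop, per-step raw and normalized scores with dominance sets."""

    times: np.ndarray
    loops: list[Loop]
    raw: pd.DataFrame                 # index time, columns loop ids
    normalized: pd.DataFrame
    net: pd.Series
    dominant: list[tuple[str, ...]]   # ranked dominant set per step
    threshold: float = 50.0
    labels: dict[str, str] = field(default_factory=dict)

    def loop(self, loop_id: str) -> Loop:
        for lp in self.loops:
            if lp.id == loop_id:
                return lp
        raise KeyError(loop_id)

    def major_series(self) -> pd.DataFrame:
        """Normalized scores of the major loops, labelled columns."""
        cols = {self.labels.get(lp.id, lp.id): self.normalized[lp.id]
                for lp in self.loops if lp.rank == "major"}
        return pd.DataFrame(cols, index=self.normalized.index)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long form: time, loop_id, loop_label, raw, normalized,
        is_dominant, net."""
        rows = []
        for step, t in enumerate(self.times):
            dom = set(self.dominant[step])
            for lp in self.loops:
                rows.append({
                    "time": t,
                    "loop_id": lp.id,
                    "loop_label": self.labels.get(lp.id, lp.id),
                    "raw": self.raw[lp.id].iloc[step],
                    "normalized": self.normalized[lp.id].iloc[step],
                    "is_dominant": lp.id in dom,
                    "net": self.net.iloc[step],
                })
        return pd.DataFrame(rows)


def dominance_profile(trajectory: Trajectory, model: ModelSpec,
                      threshold: float = 50.0,
                      labels: dict[str, str] | None = None,
                      eps: float = EPS) -> LoopScoreFrame:
    """Full pipeline: enumerate loops, score every step, normalize, net score
    and dominant sets.  Normalization runs over *all* enumerated loops (major
    and minor); reporting typically focuses on the majors."""
    if not 0 < threshold <= 100:
        raise InvalidThresholdError(f"threshold must lie in (0, 100], got {threshold}")
    loops = enumerate_loops(model)
    raw = loop_scores(trajectory, model, loops, eps)
    norm = raw.apply(lambda row: pd.Series(normalize_scores(row.values),
                                           index=row.index), axis=1)
    net = norm.sum(axis=1)
    dominant = [_dominant_from_row(norm.iloc[i], threshold)
                for i in range(len(norm))]
    if labels is None:
        try:
            from .model import label_major_loops
            labels = label_major_loops(loops)
        except Exception:   # non-devtrans models: fall back to ids
            labels = {}
    return LoopScoreFrame(times=trajectory.times, loops=loops, raw=raw,
                          normalized=norm, net=net, dominant=dominant,
                          threshold=threshold, labels=labels)


def dominance_shift_sequence(frame: LoopScoreFrame,
                             min_duration: float = 0.25) -> list[tuple[str, ...]]:
    """Ordered sequence of dominant sets, debounced: segments shorter than
    ``min_duration`` years are treated as transient chatter and dropped
    before collapsing consecutive duplicates.  Dominant sets are compared as
    unordered sets of loop ids."""
    dt = float(frame.times[1] - frame.times[0]) if len(frame.times) > 1 else 1.0
    min_steps = max(1, int(round(min_duration / dt)))
    segments: list[tuple[frozenset, int]] = []
    for dom in frame.dominant:
        key = frozenset(dom)
        if segments and segments[-1][0] == key:
            segments[-1] = (key, segments[-1][1] + 1)
        else:
            segments.append((key, 1))
    kept = [s for s in segments if s[1] >= min_steps]
    seq: list[tuple[str, ...]] = []
    for key, _n in kept:
        tup = tuple(sorted(key))
        if not seq or seq[-1] != tup:
            seq.append(tup)
    return seq


def major_loop_sequence(frame: LoopScoreFrame,
                        min_duration: float = 0.5) -> tuple[str, ...]:
    """Debounced sequence of the leading major feedback mechanism.

    At each step the major loop with the largest absolute normalized score is
    taken (``"~"`` at stationary instants); segments shorter than
    ``min_duration`` years are dropped as transient chatter and consecutive
    duplicates collapsed.  This is the phase structure a loop-score plot of
    the main mechanisms displays, and the object the parameter-continuity
    robustness argument is about.
    """
    maj = frame.major_series()
    dt = float(frame.times[1] - frame.times[0]) if len(frame.times) > 1 else 1.0
    min_steps = max(1, int(round(min_duration / dt)))
    keys = []
    for i in range(len(maj)):
        row = maj.iloc[i].abs()
        keys.append("~" if row.max() < 1e-9 else row.idxmax())
    segments: list[list] = []
    for k in keys:
        if segments and segments[-1][0] == k:
            segments[-1][1] += 1
        else:
            segments.append([k, 1])
    seq: list[str] = []
    for k, n in segments:
        if n >= min_steps and (not seq or seq[-1] != k):
            seq.append(k)
    return tuple(seq)
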