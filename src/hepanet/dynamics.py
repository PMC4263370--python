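"""Assembly and integration of the coupled network rate equations.

Each enzymatic reaction contributes the reversible two-step mechanism

    S + E  <->  C  ->  E + P        (product step reversible via k_PR)

with elementary rates

    v1 = k_C * E * prod(S_i)  -  k_CR * C          (complex formation, net)
    v2 = k_P * C              -  k_PR * E * prod(P_i)   (product formation, net)

so dS/dt collects ``-m_S v1`` terms, dP/dt ``+m_P v2`` terms, dC/dt = v1 - v2
and dE/dt = synthesis - degradation - v1 + v2.  With the constants of
:func:`hepanet.core.derive_rate_constants` the normalized reference state is
an exact equilibrium and each step's reverse/forward flux ratio equals r.

Integration uses a stiff BDF solver (the reference implementation used a
DASSL-family integrator at tolerance 1e-9) restarted at every perturbation
start time so parameter discontinuities are handled exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import NetworkModel, StructuralError, ValidationError, initialize_state
from .regulation import (
    activation_factor,
    repression_factor,
    switch_rates,
    transcription_production,
)

__all__ = [
    "PerturbationAction",
    "PerturbationSpec",
    "Trajectory",
    "SteadyStateResult",
    "assemble_rhs",
    "integrate",
    "detect_steady_state",
    "find_steady_state",
    "predict_single_reaction_steady_state",
    "predict_chain_steady_state",
    "realized_flux_fractions",
    "child_fluxes",
]

#: Default integration horizon (arbitrary time units, with convergence early-exit).
DEFAULT_T_END = 1e6
#: Default steady-state acceptance threshold on the normalized scale.
DEFAULT_EPS_SS = 1e-7
#: Divergence guard: any state beyond this aborts as unstable.
MAX_STATE = 1e6
#: Negativity guard (normalized concentrations are nonnegative).
NEG_TOL = 1e-9

_ACTION_KINDS = {
    "influx_fold", "degradation_fold", "knockout", "constant_activation",
    "demand_fold",
}


@dataclass(frozen=True)
class PerturbationAction:
    """One parameter change applied from ``start_time`` onward.

    kinds:
      * ``influx_fold``        -- multiply a flux source's phi
      * ``demand_fold``        -- multiply a sink's first-order rate
      * ``degradation_fold``   -- multiply the degradation constant of an
                                  enzyme, gene, protein or switch
      * ``knockout``           -- degradation_fold with magnitude 1000
      * ``constant_activation``-- clamp a switch's active pool at ``magnitude``
    """

    kind: str
    target: str
    magnitude: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _ACTION_KINDS:
            raise ValidationError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ValidationError("perturbation magnitude must be > 0")
        if self.kind == "knockout" and self.magnitude < 1000:
            object.__setattr__(self, "magnitude", 1000.0)


@dataclass(frozen=True)
class PerturbationSpec:
    actions: tuple[PerturbationAction, ...] = ()

    @classmethod
    def of(cls, *actions: PerturbationAction) -> "PerturbationSpec":
        return cls(tuple(actions))

    def shifted(self, dt: float) -> "PerturbationSpec":
        return PerturbationSpec(tuple(
            PerturbationAction(a.kind, a.target, a.magnitude, a.start_time + dt)
            for a in self.actions
        ))

    def __add__(self, other: "PerturbationSpec") -> "PerturbationSpec":
        return PerturbationSpec(self.actions + other.actions)

    @property
    def start_times(self) -> tuple[float, ...]:
        return tuple(sorted({a.start_time for a in self.actions}))


class _Multipliers:
    """Fold multipliers in force during one integration phase."""

    def __init__(self) -> None:
        self.source: dict[str, float] = {}
        self.sink: dict[str, float] = {}
        self.deg: dict[str, float] = {}   # enzyme/gene/protein/switch id -> fold
        self.clamp_active: dict[str, float] = {}

    def apply(self, network: NetworkModel, action: PerturbationAction) -> None:
        a = action
        if a.kind == "influx_fold":
            if a.target not in network.sources:
                raise StructuralError(f"unknown source {a.target!r}")
            self.source[a.target] = self.source.get(a.target, 1.0) * a.magnitude
        elif a.kind == "demand_fold":
            if a.target not in network.sinks:
                raise StructuralError(f"unknown sink {a.target!r}")
            self.sink[a.target] = self.sink.get(a.target, 1.0) * a.magnitude
        elif a.kind in ("degradation_fold", "knockout"):
            known = (a.target in network._enz or a.target in network.genes
                     or a.target in network.proteins or a.target in network.switches)
            if not known:
                raise StructuralError(
                    f"degradation target {a.target!r} is not an enzyme, gene, "
                    "protein or switch"
                )
            self.deg[a.target] = self.deg.get(a.target, 1.0) * a.magnitude
        elif a.kind == "constant_activation":
            if a.target not in network.switches:
                raise StructuralError(f"unknown switch {a.target!r}")
            self.clamp_active[a.target] = a.magnitude


def assemble_rhs(network: NetworkModel, multipliers: _Multipliers | None = None
                 ) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the network into a derivative function dx/dt = f(t, x).

    The returned function is deterministic and side-effect free; the
    assembly order follows the definition's entity order but every term is
    additive, so evaluation is independent of insertion order.
    """
    mult = multipliers or _Multipliers()
    d = network.definition
    idx = network.index
    n = len(idx)

    # precompiled term lists (integer indices + floats)
    sources = [(idx[s.target], s.phi * mult.source.get(s.id, 1.0))
               for s in d.sources]
    sinks = [(idx[s.target], network.sink_rates[s.id] * mult.sink.get(s.id, 1.0))
             for s in d.sinks]

    rxn_enz = []   # enzymatic reactions
    rxn_free = []  # carrier steps
    for r in d.reactions:
        rc = network.rate_constants[r.id]
        subs = [(idx[m], mu) for m, mu in r.substrates.items()]
        prods = [(idx[m], mu) for m, mu in r.products.items()]
        if r.enzyme is None:
            rxn_free.append((subs, prods, rc.k_C, rc.k_CR))
        else:
            rxn_enz.append((subs, prods, idx[f"enz.{r.enzyme}"],
                            idx[f"cx.{r.id}"], rc))

    enzymes = []
    for e in d.enzymes:
        reg = idx.resolve(e.regulated_by) if e.regulated_by else None
        enzymes.append((idx[f"enz.{e.id}"], e.turnover,
                        mult.deg.get(e.id, 1.0), reg))

    genes = []
    for g in d.genes:
        regs = [idx.resolve(ref) for ref, _ in g.regulators]
        genes.append((idx[f"mrna.{g.id}"], g, regs, mult.deg.get(g.id, 1.0)))

    proteins = [(idx[p.id], p, idx[f"mrna.{p.mrna}"], mult.deg.get(p.id, 1.0))
                for p in d.proteins]

    switches = []
    for s in d.switches:
        act = idx.resolve(s.act_driver) if s.act_driver else None
        inact = idx.resolve(s.inact_driver) if s.inact_driver else None
        synth = idx.resolve(s.synth) if s.synth else None
        clamped = s.id in mult.clamp_active
        switches.append((idx[f"{s.id}.active"], idx[f"{s.id}.inactive"], s,
                         act, inact, synth, mult.deg.get(s.id, 1.0), clamped))

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        if x.shape != (n,):
            raise ValidationError(
                f"state vector length {x.shape} != {n} states"
            )
        dx = np.zeros(n)
        for i, phi in sources:
            dx[i] += phi
        for i, k in sinks:
            dx[i] -= k * x[i]
        for subs, prods, ei, ci, rc in rxn_enz:
            s_prod = 1.0
            for i, _ in subs:
                s_prod *= x[i]
            p_prod = 1.0
            for i, _ in prods:
                p_prod *= x[i]
            v1 = rc.k_C * x[ei] * s_prod - rc.k_CR * x[ci]
            v2 = rc.k_P * x[ci] - rc.k_PR * x[ei] * p_prod
            for i, mu in subs:
                dx[i] -= mu * v1
            for i, mu in prods:
                dx[i] += mu * v2
            dx[ci] += v1 - v2
            dx[ei] += v2 - v1
        for subs, prods, kf, kr in rxn_free:
            s_prod = 1.0
            for i, _ in subs:
                s_prod *= x[i]
            p_prod = 1.0
            for i, _ in prods:
                p_prod *= x[i]
            v = kf * s_prod - kr * p_prod
            for i, mu in subs:
                dx[i] -= mu * v
            for i, mu in prods:
                dx[i] += mu * v
        for ei, k, dmult, reg in enzymes:
            syn = k if reg is None else k * x[reg]
            dx[ei] += syn - k * dmult * x[ei]
        for mi, g, regs, dmult in genes:
            levels = [max(x[j], 0.0) for j in regs]
            dx[mi] += transcription_production(g, levels) - g.k_d * dmult * x[mi]
        for pi, p, mi, dmult in proteins:
            dx[pi] += p.k_d * x[mi] - p.k_d * dmult * x[pi]
        for ai, ii, s, act, inact, synth, dmult, clamped in switches:
            da, di = switch_rates(
                s, x[ai], x[ii],
                act_level=x[act] if act is not None else 1.0,
                inact_level=x[inact] if inact is not None else 1.0,
                synth_level=x[synth] if synth is not None else 1.0,
                deg_mult=dmult,
            )
            if clamped:
                da = 0.0
            dx[ai] += da
            dx[ii] += di
        return dx

    return rhs


@dataclass
class Trajectory:
    """A simulated time course of all normalized states."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    labels: tuple[str, ...]
    events: tuple[float, ...] = ()
    #: derivative function in force at the end of the run (for residual checks)
    rhs: Callable[[float, np.ndarray], np.ndarray] | None = field(
        default=None, repr=False)
    network: NetworkModel | None = field(default=None, repr=False)
    failure_mode: str = "none"       # none | divergence | negativity | solver-failure
    failure_time: float | None = None

    def value(self, name: str, t_index: int = -1) -> float:
        if self.network is None:
            raise ValueError("trajectory carries no network reference")
        return float(self.states[t_index, self.network.index.resolve(name)])

    def to_frame(self):
        """Tidy DataFrame (time, variable, value)."""
        import pandas as pd

        n_t = len(self.times)
        return pd.DataFrame({
            "time": np.repeat(self.times, len(self.labels)),
            "variable": list(self.labels) * n_t,
            "value": self.states.reshape(-1),
        })


@dataclass
class SteadyStateResult:
    converged: bool
    state: np.ndarray
    t_reached: float
    residual: float
    fold_changes: dict[str, float]
    mode: str = "none"   # none | divergence | negativity | non-convergence | solver-failure
    failure_time: float | None = None

    def fold(self, name: str, network: NetworkModel) -> float:
        return self.fold_changes[network.index.resolve_label(name)]


def _fold_changes(network: NetworkModel, state: np.ndarray) -> dict[str, float]:
    baseline = initialize_state(network)
    return {
        lab: float(state[i] / baseline[i])
        for i, lab in enumerate(network.index.labels)
    }


def _guard(x: np.ndarray) -> str:
    if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > MAX_STATE:
        return "divergence"
    if np.min(x) < -NEG_TOL:
        return "negativity"
    return "none"


def integrate(network: NetworkModel,
              perturbation: PerturbationSpec | None = None,
              t_end: float = DEFAULT_T_END,
              rtol: float = 1e-9,
              atol: float = 1e-12,
              x0: np.ndarray | None = None,
              eps_ss: float = DEFAULT_EPS_SS,
              method: str = "BDF") -> Trajectory:
    """Integrate the network over [0, t_end] with perturbations applied.

    Integration restarts at every perturbation start time (events are exact).
    Within the final stretch the run exits early once the derivative max-norm
    and the relative state change over the last chunk both drop below
    ``eps_ss``.  Divergence or solver failure is recorded on the returned
    trajectory, never raised.
    """
    if t_end <= 0:
        raise ValidationError("t_end must be > 0")
    if rtol <= 0 or atol <= 0:
        raise ValidationError("tolerances must be > 0")
    spec = perturbation or PerturbationSpec()
    x = initialize_state(network) if x0 is None else np.asarray(x0, float).copy()

    event_times = sorted({t for t in spec.start_times if 0.0 < t < t_end})
    bounds = [0.0] + event_times + [t_end]

    all_t: list[np.ndarray] = [np.array([0.0])]
    all_x: list[np.ndarray] = [x.copy()[None, :]]
    rhs = assemble_rhs(network)
    failure_mode, failure_time = "none", None

    for ta, tb in zip(bounds[:-1], bounds[1:]):
        mult = _Multipliers()
        for a in spec.actions:
            if a.start_time <= ta:
                mult.apply(network, a)
        # clamped pools snap to their target value at the phase start
        for sid, val in mult.clamp_active.items():
            x[network.index[f"{sid}.active"]] = val
        rhs = assemble_rhs(network, mult)

        t = ta
        dt = min(100.0, tb - ta)
        while t < tb - 1e-12:
            t_next = min(t + dt, tb)
            sol = solve_ivp(rhs, (t, t_next), x, method=method,
                            rtol=rtol, atol=atol, dense_output=False)
            if not sol.success:
                failure_mode, failure_time = "solver-failure", float(sol.t[-1])
                x = sol.y[:, -1]
                all_t.append(sol.t[1:])
                all_x.append(sol.y.T[1:])
                break
            x_prev = x
            x = sol.y[:, -1].copy()
            all_t.append(sol.t[1:])
            all_x.append(sol.y.T[1:])
            g = _guard(x)
            if g != "none":
                failure_mode, failure_time = g, float(t_next)
                break
            t = t_next
            res = float(np.max(np.abs(rhs(t, x))))
            rel = float(np.max(np.abs(x - x_prev) / np.maximum(np.abs(x), 1e-6)))
            if res < eps_ss and rel < eps_ss:
                break  # settled; remaining time in this phase is a no-op
            dt *= 4.0
        if failure_mode != "none":
            break

    times = np.concatenate(all_t)
    states = np.vstack(all_x)
    return Trajectory(times=times, states=states, labels=network.index.labels,
                      events=tuple(event_times), rhs=rhs, network=network,
                      failure_mode=failure_mode, failure_time=failure_time)


def detect_steady_state(trajectory: Trajectory,
                        eps_ss: float = DEFAULT_EPS_SS,
                        window: float = 0.1) -> SteadyStateResult:
    """Decide whether a trajectory has settled.

    Converged iff the derivative max-norm at the final state and the maximal
    relative state change over the trailing ``window`` fraction of elapsed
    time are both below ``eps_ss`` (and no divergence guard fired).
    """
    if trajectory.network is None or trajectory.rhs is None:
        raise ValueError("trajectory must carry its network and rhs")
    net = trajectory.network
    x_end = trajectory.states[-1]
    t_end = float(trajectory.times[-1])
    residual = float(np.max(np.abs(trajectory.rhs(t_end, x_end))))

    t_lo = t_end * (1.0 - window)
    mask = trajectory.times >= t_lo
    win = trajectory.states[mask]
    rel = float(np.max(np.abs(win - x_end) / np.maximum(np.abs(x_end), 1e-6))) \
        if len(win) else math.inf

    if trajectory.failure_mode != "none":
        return SteadyStateResult(False, x_end, t_end, residual,
                                 _fold_changes(net, x_end),
                                 mode=trajectory.failure_mode,
                                 failure_time=trajectory.failure_time)
    ok = residual < eps_ss and rel < eps_ss
    return SteadyStateResult(ok, x_end, t_end, residual,
                             _fold_changes(net, x_end),
                             mode="none" if ok else "non-convergence",
                             failure_time=None if ok else t_end)


def find_steady_state(network: NetworkModel,
                      perturbation: PerturbationSpec | None = None,
                      **kwargs) -> SteadyStateResult:
    """Integrate to the post-perturbation steady state and classify it."""
    eps_ss = kwargs.get("eps_ss", DEFAULT_EPS_SS)
    traj = integrate(network, perturbation, **kwargs)
    return detect_steady_state(traj, eps_ss=eps_ss)


# ---------------------------------------------------------------------------
# Closed-form single-reaction / chain steady states
# ---------------------------------------------------------------------------


class SingleReactionSteadyState(NamedTuple):
    S: float
    E: float
    C: float
    P: float
    f_star: float


def predict_single_reaction_steady_state(r: float, f: float = 1.0,
                                         w: float = 1.0,
                                         influx_fold: float = 1.0,
                                         efflux_demand: float = 1.0
                                         ) -> SingleReactionSteadyState:
    """Closed-form steady state of one reaction after an influx/demand change.

    The reaction is initialized at the normalized baseline (S=E=P=1, C=w)
    carrying throughput f; its substrate influx is then scaled by
    ``influx_fold`` (a) and the first-order product demand by
    ``efflux_demand`` (d).  Solving the steady-state balances with the
    derived constants gives::

        E* = 1
        P* = a / d
        C* = w (a (1 - r) + r P*)
        S* = a (1 - r^2) + r^2 P*

    The result depends only on the fold-changes a, d and on (r, w) -- never
    on the absolute baseline flux, so jointly scaling influx and demand by
    any c > 0 leaves it unchanged.  ``f_star`` is the realized fraction
    against siblings held at baseline: f a / (f a + 1 - f).
    """
    if not (0.0 <= r < 1.0):
        raise ValidationError(f"r={r} outside [0, 1)")
    if w <= 0 or not (0.0 < f <= 1.0):
        raise ValidationError("need w > 0 and f in (0, 1]")
    if influx_fold <= 0 or efflux_demand <= 0:
        raise ValidationError("influx_fold and efflux_demand must be > 0")
    a, d = influx_fold, efflux_demand
    P = a / d
    E = 1.0
    C = w * (a * (1.0 - r) + r * P * E)
    S = a * (1.0 - r * r) + r * r * P
    if min(S, C, P) <= 0:
        raise ValidationError("no positive steady state for these folds")
    f_star = f * a / (f * a + (1.0 - f))
    return SingleReactionSteadyState(S, E, C, P, f_star)


def predict_chain_steady_state(rs: Sequence[float], ws: Sequence[float],
                               influx_fold: float = 1.0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form steady state of a linear chain with terminal first-order demand.

    Returns (metabolite levels upstream-to-terminal, complex levels per
    reaction).  The terminal product settles at the influx fold a; walking
    upstream, X_i = a (1 - r_i^2) + r_i^2 X_{i+1} and C_i = w_i (a (1 - r_i)
    + r_i X_{i+1}); all free enzymes return to 1.
    """
    if len(rs) != len(ws):
        raise ValidationError("need one (r, w) pair per reaction")
    a = influx_fold
    n = len(rs)
    mets = np.empty(n + 1)
    cxs = np.empty(n)
    mets[n] = a
    for i in range(n - 1, -1, -1):
        r, w = rs[i], ws[i]
        cxs[i] = w * (a * (1.0 - r) + r * mets[i + 1])
        mets[i] = a * (1.0 - r * r) + r * r * mets[i + 1]
    return mets, cxs


# ---------------------------------------------------------------------------
# Realized flux fractions at a steady state
# ---------------------------------------------------------------------------


def child_fluxes(network: NetworkModel, state: np.ndarray, parent: str
                 ) -> dict[str, float]:
    """Net flux drawn from ``parent`` by each of its consumers at ``state``."""
    idx = network.index
    out: dict[str, float] = {}
    for r in network.definition.reactions:
        if parent not in r.substrates:
            continue
        rc = network.rate_constants[r.id]
        s_prod = 1.0
        for m in r.substrates:
            s_prod *= state[idx[m]]
        if r.enzyme is None:
            p_prod = 1.0
            for m in r.products:
                p_prod *= state[idx[m]]
            v = rc.k_C * s_prod - rc.k_CR * p_prod
        else:
            v = (rc.k_C * state[idx[f"enz.{r.enzyme}"]] * s_prod
                 - rc.k_CR * state[idx[f"cx.{r.id}"]])
        out[r.id] = r.substrates[parent] * v
    for s in network.definition.sinks:
        if s.target == parent:
            out[s.id] = network.sink_rates[s.id] * state[idx[parent]]
    return out


def realized_flux_fractions(network: NetworkModel, state: np.ndarray,
                            parent: str) -> dict[str, float]:
    """Realized fractions f* = child flux / total parent efflux at ``state``."""
    fluxes = child_fluxes(network, state, parent)
    if not fluxes:
        raise StructuralError(f"{parent!r} has no consumers")
    total = sum(fluxes.values())
    if abs(total) < 1e-300:
        raise ValidationError(
            f"total efflux of {parent!r} is zero; fractions undefined"
        )
    return {cid: v / total for cid, v in fluxes.items()}
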