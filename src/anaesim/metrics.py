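"""Outcome measures extracted from simulated traces.

The headline measure is t90 — the time for a compartment's partial pressure
to reach 90% of a reference pressure.  The reference convention matters and
is explicit everywhere:

``"inspired"``
    the inspired partial pressure of the first exposure phase — the true
    equilibrium of this closed, non-metabolizing system;
``"end_of_exposure"``
    the compartment's own pressure at the end of the last nonzero-P_I phase;
a number
    a fixed reference in mmHg (e.g. a clinical surgical-plane pressure).

Crossing times are located by monotone bracketing with linear interpolation
between dense-output samples (sub-grid accuracy; the default 0.01-min grid
comfortably supports 0.1-min reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .physiology import Agent, CirculationParams, GasPhase
from .simulate import Protocol, SolverOptions, TimeSeries, simulate

__all__ = [
    "EquilibrationResult",
    "resolve_reference",
    "t90",
    "time_to_pressure",
    "equilibration_fraction",
    "crossover_shunt",
]


@dataclass(frozen=True)
class EquilibrationResult:
    """Outcome of a fractional-equilibration query.

    ``time`` is None when the trace never reaches fraction*reference within
    the simulated horizon ("not reached") — e.g. the reptilian presets within
    a 200-min anaesthetic.
    """

    compartment: str
    reference_pressure: float
    fraction: float
    time: float | None

    @property
    def reached(self) -> bool:
        return self.time is not None


def _first_crossing(times: np.ndarray, trace: np.ndarray, threshold: float) -> float | None:
    if trace[0] >= threshold:
        return float(times[0])
    above = np.nonzero(trace >= threshold)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = trace[i - 1], trace[i]
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def resolve_reference(ts: TimeSeries, compartment: str, reference) -> float:
    """Turn a reference spec (number | 'inspired' | 'end_of_exposure') into mmHg."""
    if isinstance(reference, (int, float)):
        return float(reference)
    if reference == "inspired":
        phases = ts.metadata.get("protocol", {}).get("phases")
        if not phases:
            raise ValueError("series metadata lacks a protocol; pass a numeric reference")
        return float(phases[0][1])
    if reference == "end_of_exposure":
        phases = ts.metadata.get("protocol", {}).get("phases")
        if not phases:
            raise ValueError("series metadata lacks a protocol; pass a numeric reference")
        t_end = 0.0
        for duration, p_i in phases:
            if p_i > 0:
                t_end = t_end + duration
            else:
                break
        trace = ts.pressure(compartment)
        return float(np.interp(t_end, ts.times, trace))
    raise ValueError(f"unknown reference convention {reference!r}")


def t90(
    ts: TimeSeries,
    compartment: str = "SA",
    reference="inspired",
    fraction: float = 0.9,
) -> EquilibrationResult:
    """First time the compartment reaches ``fraction`` of the reference pressure."""
    if ts.times.size == 0:
        raise ValueError("empty time series")
    ref = resolve_reference(ts, compartment, reference)
    if ref <= 0:
        raise ValueError("reference pressure must be positive")
    trace = ts.pressure(compartment)
    return EquilibrationResult(
        compartment=compartment,
        reference_pressure=ref,
        fraction=fraction,
        time=_first_crossing(ts.times, trace, fraction * ref),
    )


def time_to_pressure(ts: TimeSeries, compartment: str, threshold: float) -> float | None:
    """First time the compartment crosses an absolute threshold (mmHg).

    Returns 0 if the initial state already meets it, None if never reached.
    """
    if ts.times.size == 0:
        raise ValueError("empty time series")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if threshold == 0:
        return 0.0
    return _first_crossing(ts.times, ts.pressure(compartment), threshold)


def equilibration_fraction(
    ts: TimeSeries, compartment: str, t: float, reference="inspired"
) -> float:
    """P(t)/reference for a compartment, t inside the simulated horizon."""
    if ts.times.size == 0:
        raise ValueError("empty time series")
    if not (ts.times[0] <= t <= ts.times[-1]):
        raise ValueError(f"t={t} outside simulated horizon [{ts.times[0]}, {ts.times[-1]}]")
    ref = resolve_reference(ts, compartment, reference)
    return float(np.interp(t, ts.times, ts.pressure(compartment))) / ref


def _t90_with_extension(
    agent: Agent,
    gas: GasPhase,
    params: CirculationParams,
    p_i: float,
    compartment: str,
    grid: float,
    horizon: float,
    max_horizon: float,
    solver: SolverOptions | None,
) -> float | None:
    """t90 vs inspired pressure, doubling the horizon until the crossing is found."""
    while True:
        ts = simulate(agent, gas, params, Protocol.washin(horizon, p_i, grid), solver)
        res = t90(ts, compartment, reference="inspired")
        if res.reached or horizon >= max_horizon:
            return res.time
        horizon *= 2.0


def crossover_shunt(
    agent_a: Agent,
    agent_b: Agent,
    gas: GasPhase,
    params: CirculationParams,
    shunt_grid,
    P_I: float = 30.0,
    compartment: str = "SA",
    output_grid: float = 0.02,
    refine_tol: float = 0.005,
    initial_horizon: float = 200.0,
    max_horizon: float = 20_000.0,
    solver: SolverOptions | None = None,
) -> float | None:
    """Smallest s_RL at which agent_b's t90 is no longer shorter than agent_a's.

    agent_b must be the faster agent (shorter t90) at zero shunt — e.g. the
    less-soluble sevoflurane versus isoflurane.  The grid is scanned in
    order; the first bracketing interval is refined by bisection to
    ``refine_tol``.  Returns None when no crossover occurs within the grid.
    """
    if (agent_a.beta_b, agent_a.beta_T) == (agent_b.beta_b, agent_b.beta_T):
        raise ValueError("agents are identical; no crossover is defined")
    grid = [float(s) for s in shunt_grid]
    if any(not 0.0 <= s < 1.0 for s in grid) or sorted(grid) != grid:
        raise ValueError("shunt grid must be monotone within [0, 1)")

    def gap(s_rl: float) -> float | None:
        """t90(b) - t90(a) at shunt s_rl; positive once b is no longer faster."""
        p = _dc_replace(params, shunt=_dc_replace(params.shunt, s_RL=s_rl))
        t_a = _t90_with_extension(
            agent_a, gas, p, P_I, compartment, output_grid,
            initial_horizon, max_horizon, solver,
        )
        t_b = _t90_with_extension(
            agent_b, gas, p, P_I, compartment, output_grid,
            initial_horizon, max_horizon, solver,
        )
        if t_a is None or t_b is None:
            return None
        return t_b - t_a

    g0 = gap(grid[0])
    if g0 is None:
        return None
    if g0 >= 0 and grid[0] == 0.0:
        raise ValueError("agent_b must be strictly faster than agent_a at zero shunt")
    prev_s, prev_g = grid[0], g0
    for s in grid[1:]:
        g = gap(s)
        if g is None:
            return None
        if g >= 0:
            lo, hi = prev_s, s
            while hi - lo > refine_tol:
                mid = 0.5 * (lo + hi)
                gm = gap(mid)
                if gm is None or gm >= 0:
                    hi = mid
                else:
                    lo = mid
            return hi
        prev_s, prev_g = s, g
    return None
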