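"""Integrate the circulation model over multi-phase exposure protocols.

A protocol is a sequence of constant-inspired-pressure phases (wash-in,
maintenance, washout).  Each phase is integrated separately with a
stiff-capable solver and the phases are concatenated with state continuity,
so the inspired-pressure discontinuity never crosses an integration step.
The system is deterministic: identical inputs and solver settings give
identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import __version__
from .ode import STATE_COMPARTMENTS, EffectiveCapacities, assemble_system, compartment_index
from .physiology import Agent, CirculationParams, GasPhase

__all__ = ["Protocol", "SolverOptions", "TimeSeries", "IntegrationError", "simulate", "washout"]


class IntegrationError(RuntimeError):
    """The ODE solver failed to meet its tolerances; carries diagnostics."""


@dataclass(frozen=True)
class Protocol:
    """Piecewise-constant inspired partial-pressure schedule.

    ``phases`` is an ordered tuple of (duration_min, P_I_mmHg);
    ``output_grid`` the reporting time step in minutes (default 0.01, chosen
    so threshold-crossing metrics resolve the 0.1-min reporting precision).
    """

    phases: tuple[tuple[float, float], ...]
    output_grid: float = 0.01

    def __post_init__(self) -> None:
        if len(self.phases) == 0:
            raise ValueError("protocol must contain at least one phase")
        phases = tuple((float(d), float(p)) for d, p in self.phases)
        object.__setattr__(self, "phases", phases)
        for duration, p_i in phases:
            if duration <= 0:
                raise ValueError("phase durations must be positive")
            if p_i < 0:
                raise ValueError("inspired pressures must be non-negative")
        if self.output_grid <= 0:
            raise ValueError("output grid must be positive")

    @classmethod
    def washin(cls, duration: float, P_I: float, output_grid: float = 0.01) -> "Protocol":
        return cls(((duration, P_I),), output_grid)

    @classmethod
    def washin_washout(
        cls, washin: float, P_I: float, washout: float, output_grid: float = 0.01
    ) -> "Protocol":
        return cls(((washin, P_I), (washout, 0.0)), output_grid)

    @property
    def duration(self) -> float:
        return sum(d for d, _ in self.phases)

    @property
    def max_inspired(self) -> float:
        return max(p for _, p in self.phases)

    def inspired_at(self, t: float) -> float:
        """Inspired pressure at time t (phase boundaries belong to the later phase)."""
        edge = 0.0
        for duration, p_i in self.phases:
            edge += duration
            if t < edge:
                return p_i
        return self.phases[-1][1]

    def to_dict(self) -> dict:
        return {"phases": [list(p) for p in self.phases], "output_grid": self.output_grid}

    @classmethod
    def from_dict(cls, data: dict) -> "Protocol":
        return cls(
            tuple(tuple(p) for p in data["phases"]),
            data.get("output_grid", 0.01),
        )


@dataclass(frozen=True)
class SolverOptions:
    """Integration settings.

    LSODA switches automatically to a stiff (BDF) method; the small
    ventricular pools (0.75 mL) against the 600-mL tissue pool make the
    system moderately stiff.  Tolerances are tight because equilibration
    times are reported to 0.1 min.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10  # mmHg

    def to_dict(self) -> dict:
        return {"method": self.method, "rtol": self.rtol, "atol": self.atol}


@dataclass
class TimeSeries:
    """Partial-pressure traces for every compartment on a common time grid.

    ``pressures`` has shape (8, n) in the fixed state order
    (L, PV, LV, SA, T, SV, RV, PA); ``times`` is strictly increasing, in
    minutes.  ``metadata`` records agent, circulation, protocol and solver
    settings so a run can be reproduced exactly.
    """

    times: np.ndarray
    pressures: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.pressures.shape != (len(STATE_COMPARTMENTS), self.times.size):
            raise ValueError("pressures must have shape (8, len(times))")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def pressure(self, compartment: str) -> np.ndarray:
        return self.pressures[compartment_index(compartment)]

    @property
    def final_state(self) -> np.ndarray:
        return self.pressures[:, -1].copy()

    def to_frame(self, tidy: bool = True) -> pd.DataFrame:
        if tidy:
            n = self.times.size
            return pd.DataFrame(
                {
                    "time_min": np.tile(self.times, len(STATE_COMPARTMENTS)),
                    "compartment": np.repeat(STATE_COMPARTMENTS, n),
                    "pressure_mmHg": self.pressures.ravel(),
                }
            )
        wide = pd.DataFrame({"time_min": self.times})
        for i, code in enumerate(STATE_COMPARTMENTS):
            wide[code] = self.pressures[i]
        return wide

    def to_csv(self, path, tidy: bool = True, float_format: str = "%.10g") -> None:
        self.to_frame(tidy=tidy).to_csv(path, index=False, float_format=float_format)

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


def _integrate_phase(
    system, y0: np.ndarray, duration: float, grid: float, solver: SolverOptions
) -> tuple[np.ndarray, np.ndarray, dict]:
    n_steps = max(1, int(round(duration / grid)))
    t_eval = np.linspace(0.0, duration, n_steps + 1)
    sol = solve_ivp(
        system.rhs,
        (0.0, duration),
        y0,
        method=solver.method,
        t_eval=t_eval,
        jac=system.jacobian,
        rtol=solver.rtol,
        atol=solver.atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver {solver.method} failed after {sol.t[-1]:.4g} min: {sol.message}"
        )
    stats = {"nfev": int(sol.nfev), "njev": int(sol.njev), "status": int(sol.status)}
    return sol.t, sol.y, stats


def simulate(
    agent: Agent,
    gas: GasPhase,
    params: CirculationParams,
    protocol: Protocol,
    solver: SolverOptions | None = None,
    initial_state: np.ndarray | None = None,
) -> TimeSeries:
    """Run the model over a protocol and return dense per-compartment traces.

    The initial condition defaults to the anaesthetic-naive animal (all
    pressures zero).
    """
    solver = solver or SolverOptions()
    y = (
        np.zeros(len(STATE_COMPARTMENTS))
        if initial_state is None
        else np.asarray(initial_state, dtype=float).copy()
    )
    times: list[np.ndarray] = []
    traces: list[np.ndarray] = []
    stats: list[dict] = []
    t0 = 0.0
    for duration, p_i in protocol.phases:
        system = assemble_system(agent, gas, params, p_i)
        t, ytraj, st = _integrate_phase(system, y, duration, protocol.output_grid, solver)
        if times:  # drop the duplicated boundary sample; state is continuous
            t, ytraj = t[1:], ytraj[:, 1:]
        times.append(t0 + t)
        traces.append(ytraj)
        stats.append(st)
        y = ytraj[:, -1].copy() if ytraj.size else y
        t0 += duration

    metadata = {
        "package": "anaesim",
        "version": __version__,
        "agent": agent.to_dict(),
        "gas": gas.to_dict(),
        "params": params.to_dict(),
        "protocol": protocol.to_dict(),
        "solver": solver.to_dict(),
        "solver_stats": stats,
        "state_order": list(STATE_COMPARTMENTS),
    }
    return TimeSeries(np.concatenate(times), np.hstack(traces), metadata)


def washout(
    timeseries: TimeSeries,
    agent: Agent,
    gas: GasPhase,
    params: CirculationParams,
    duration: float,
    solver: SolverOptions | None = None,
) -> TimeSeries:
    """Continue a completed exposure with P_I = 0 and append to the series."""
    grid = timeseries.metadata.get("protocol", {}).get("output_grid", 0.01)
    tail = simulate(
        agent,
        gas,
        params,
        Protocol.washin(duration, 0.0, output_grid=grid),
        solver=solver,
        initial_state=timeseries.final_state,
    )
    t_end = timeseries.times[-1]
    joined = TimeSeries(
        np.concatenate([timeseries.times, t_end + tail.times[1:]]),
        np.hstack([timeseries.pressures, tail.pressures[:, 1:]]),
        dict(timeseries.metadata),
    )
    phases = joined.metadata.get("protocol", {}).get("phases", [])
    joined.metadata["protocol"] = {
        "phases": [list(p) for p in phases] + [[duration, 0.0]],
        "output_grid": grid,
    }
    return joined
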