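"""Packaged scenario presets, the agent library, and the sweep engine.

Presets ship as YAML data (``presets/presets.yaml``) and cover the standard
comparative runs: the 1-kg rabbit, the terrapin-like slow circulation, the
representative mammal/reptile pair, convection comparisons and the shunting
circulation.  ``run_sweep`` regenerates the parameter-sensitivity curves
(ventilation, cardiac output, lung volume, shunt severity, and solubility
along a constant tissue-to-blood ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .flows import pulmonary_bypass_to_srl
from .metrics import t90
from .physiology import Agent, CirculationParams, GasPhase
from .simulate import Protocol, SolverOptions, TimeSeries, simulate

__all__ = [
    "AGENTS",
    "ISOFLURANE_TISSUE_BLOOD_RATIO",
    "Scenario",
    "SweepSpec",
    "PresetNotFoundError",
    "agent_library",
    "available_presets",
    "load_preset",
    "run_sweep",
    "fig2b_sweep",
    "fig4b_sweep",
    "fig4d_sweep",
    "fig5c_sweep",
]

#: The three-agent library.  Isoflurane's coefficients are used throughout
#: the single-agent runs; halothane and sevoflurane take the upper and lower
#: endpoints of the scenario capacitance ranges, matching the known solubility
#: ordering (lambda_b: halothane ~2.4 > isoflurane ~1.3 > sevoflurane ~0.64).
AGENTS: dict[str, Agent] = {
    "halothane": Agent("halothane", beta_b=0.00278, beta_T=0.0099),
    "isoflurane": Agent("isoflurane", beta_b=0.001528, beta_T=0.00461),
    "sevoflurane": Agent("sevoflurane", beta_b=0.00074, beta_T=0.0025),
}

#: beta_T / beta_b for isoflurane; constant-ratio solubility sweeps use it.
ISOFLURANE_TISSUE_BLOOD_RATIO = AGENTS["isoflurane"].beta_T / AGENTS["isoflurane"].beta_b


def agent_library() -> dict[str, Agent]:
    """The packaged anaesthetic agents (halothane, isoflurane, sevoflurane)."""
    return dict(AGENTS)


class PresetNotFoundError(KeyError):
    pass


@dataclass(frozen=True)
class Scenario:
    """A fully specified, reproducible model run."""

    id: str
    description: str
    agents: tuple[str, ...]
    params: CirculationParams
    protocol: Protocol
    metric: dict = field(default_factory=lambda: {"compartment": "SA", "reference": "inspired"})

    def run(
        self,
        agent: str | Agent | None = None,
        gas: GasPhase | None = None,
        solver: SolverOptions | None = None,
    ) -> TimeSeries:
        """Simulate the scenario (default agent: the preset's first agent)."""
        if agent is None:
            agent = self.agents[0]
        if isinstance(agent, str):
            try:
                agent = AGENTS[agent]
            except KeyError:
                raise KeyError(
                    f"unknown agent {agent!r}; available: {sorted(AGENTS)}"
                ) from None
        ts = simulate(agent, gas or GasPhase(), self.params, self.protocol, solver)
        ts.metadata["scenario"] = self.id
        return ts

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "description": self.description,
            "agents": list(self.agents),
            "params": self.params.to_dict(),
            "protocol": self.protocol.to_dict(),
            "metric": dict(self.metric),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        return cls(
            id=data["id"],
            description=data.get("description", ""),
            agents=tuple(data["agents"]),
            params=CirculationParams.from_dict(data["params"]),
            protocol=Protocol.from_dict(data["protocol"]),
            metric=dict(data.get("metric", {"compartment": "SA", "reference": "inspired"})),
        )


def _load_raw() -> dict:
    text = resources.files("anaesim").joinpath("presets/presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(_load_raw()["presets"])


def load_preset(preset_id: str) -> Scenario:
    raw = _load_raw()["presets"]
    if preset_id not in raw:
        raise PresetNotFoundError(
            f"unknown preset {preset_id!r}; available: {', '.join(sorted(raw))}"
        )
    entry = dict(raw[preset_id])
    entry["id"] = preset_id
    return Scenario.from_dict(entry)


@dataclass(frozen=True)
class SweepSpec:
    """One swept parameter over a fixed base scenario.

    ``parameter`` is one of Q_tot, V_dot_L, L, s_RL, pulmonary_bypass, or
    beta_b (the latter sweeping solubility at the constant isoflurane
    tissue-to-blood capacitance ratio).  ``pulmonary_bypass`` values are
    mapped through flows.pulmonary_bypass_to_srl.
    """

    parameter: str
    grid: tuple[float, ...]
    base: Scenario
    agent: str = "isoflurane"
    compartment: str = "SA"
    reference = "inspired"
    fixed: dict = field(default_factory=dict)  # extra parameter overrides

    _PARAMS = ("Q_tot", "V_dot_L", "L", "s_RL", "pulmonary_bypass", "beta_b")

    def __post_init__(self) -> None:
        if self.parameter not in self._PARAMS:
            raise ValueError(f"parameter must be one of {self._PARAMS}")
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))


def _apply(params: CirculationParams, name: str, value: float) -> CirculationParams:
    if name == "s_RL":
        return _dc_replace(params, shunt=_dc_replace(params.shunt, s_RL=value))
    if name == "pulmonary_bypass":
        return _dc_replace(
            params, shunt=_dc_replace(params.shunt, s_RL=pulmonary_bypass_to_srl(value))
        )
    return _dc_replace(params, **{name: value})


def run_sweep(
    spec: SweepSpec,
    gas: GasPhase | None = None,
    solver: SolverOptions | None = None,
    output_grid: float = 0.02,
    max_horizon: float = 20_000.0,
) -> pd.DataFrame:
    """Evaluate t90 at every grid point; one independent row per point.

    Rows where the integration fails are flagged in the ``status`` column and
    the sweep continues.  The horizon is extended (doubling) until the
    crossing is found or ``max_horizon`` is reached ("not_reached").
    """
    gas = gas or GasPhase()
    base_agent = AGENTS[spec.agent]
    rows = []
    for value in spec.grid:
        params, agent = spec.base.params, base_agent
        try:
            for name, fv in spec.fixed.items():
                params = _apply(params, name, fv)
            if spec.parameter == "beta_b":
                agent = Agent(
                    f"beta_b={value:g}",
                    beta_b=value,
                    beta_T=value * ISOFLURANE_TISSUE_BLOOD_RATIO,
                )
            else:
                params = _apply(params, spec.parameter, value)
            p_i = spec.base.protocol.phases[0][1]
            horizon = spec.base.protocol.duration
            time = None
            while True:
                ts = simulate(
                    agent, gas, params, Protocol.washin(horizon, p_i, output_grid), solver
                )
                res = t90(ts, spec.compartment, reference="inspired")
                if res.reached:
                    time = res.time
                    break
                if horizon >= max_horizon:
                    break
                horizon = min(2.0 * horizon, max_horizon)
            status = "ok" if time is not None else "not_reached"
        except Exception as exc:  # integration failure: flag the row, continue
            time, status = None, f"error: {exc}"
        rows.append(
            {
                "parameter": spec.parameter,
                "value": value,
                "agent": agent.name,
                "compartment": spec.compartment,
                "t90_min": time,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def _log_grid(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(np.logspace(np.log10(lo), np.log10(hi), n))


def fig2b_sweep(n: int = 50) -> SweepSpec:
    """Solubility sweep (beta_b 1e-4..4e-3, constant beta_T/beta_b ratio)."""
    return SweepSpec("beta_b", _log_grid(1e-4, 4e-3, n), load_preset("fig2b_terrapin"))


def fig4b_sweep(Q_tot: float = 100.0, L: float = 75.0, n: int = 50) -> SweepSpec:
    """Ventilation sweep 10..1000 mL/min at fixed cardiac output and lung volume."""
    return SweepSpec(
        "V_dot_L",
        _log_grid(10, 1000, n),
        load_preset("fig4a_vent50"),
        fixed={"Q_tot": Q_tot, "L": L},
    )


def fig4d_sweep(V_dot_L: float = 100.0, L: float = 75.0, n: int = 50) -> SweepSpec:
    """Cardiac-output sweep 10..600 mL/min at fixed ventilation and lung volume."""
    return SweepSpec(
        "Q_tot",
        _log_grid(10, 600, n),
        load_preset("fig4c_q50"),
        fixed={"V_dot_L": V_dot_L, "L": L},
    )


def fig5c_sweep(agent: str = "isoflurane", n: int = 19) -> SweepSpec:
    """Shunt-severity sweep 0..0.9 (pulmonary bypass fraction) per agent."""
    return SweepSpec(
        "pulmonary_bypass",
        tuple(np.linspace(0.0, 0.9, n)),
        load_preset("fig5_shunt"),
        agent=agent,
    )
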