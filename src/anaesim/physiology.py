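"""Domain types and unit conversions for inhaled-anaesthetic transport.

The convective transport of an inhaled anaesthetic is governed by capacitance
coefficients: the amount of gas (expressed as mL at standard temperature and
pressure, dry — STPD) stored per mL of a phase per mmHg of partial pressure.
The familiar blood-gas and tissue-gas partition coefficients are the ratios of
the blood and tissue capacitance coefficients to the gas-phase capacitance
coefficient, which itself follows from the ideal-gas law.

Units discipline used throughout the package:

* flows and ventilation: mL min⁻¹ (values quoted per kg refer to the 1-kg
  reference animal, so they are used as absolute flows),
* volumes: mL; time: min; partial pressures: mmHg,
* gas amounts: mL STPD; capacitance coefficients: mL_STPD mL⁻¹ mmHg⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "GAS_CONSTANT",
    "MMHG_IN_PA",
    "STPD_MOLAR_VOLUME",
    "BAROMETRIC_PRESSURE",
    "BODY_TEMPERATURE",
    "ZERO_CELSIUS",
    "gas_capacitance",
    "molar_gas_capacitance",
    "saturated_water_vapour_pressure",
    "stpd_ventilation_factor",
    "percent_to_mmhg",
    "mmhg_to_percent",
    "partition_coefficient",
    "agent_from_partition",
    "Agent",
    "GasPhase",
    "CompartmentVolumes",
    "ShuntSpec",
    "CirculationParams",
    "FlowSolution",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
MMHG_IN_PA = 133.322  # Pa per mmHg
STPD_MOLAR_VOLUME = 22_414.0  # mL mol^-1 at STPD
BAROMETRIC_PRESSURE = 760.0  # mmHg
BODY_TEMPERATURE = 37.0  # deg C, mammalian reference
ZERO_CELSIUS = 273.15  # K


def _check_temperature(temperature: float) -> float:
    if temperature <= -ZERO_CELSIUS:
        raise ValueError(
            f"temperature must exceed absolute zero (-273.15 C), got {temperature}"
        )
    return temperature + ZERO_CELSIUS


def gas_capacitance(temperature: float = BODY_TEMPERATURE) -> float:
    """Gas-phase capacitance coefficient beta_g, mL_STPD mL^-1 mmHg^-1.

    From the ideal-gas law: 1 mmHg of partial pressure corresponds to a molar
    concentration of (1 mmHg in Pa)/(R T) which is converted to mL STPD of gas
    per mL of gas phase.  At 37 C this is ~1.159e-3 mL_STPD mL^-1 mmHg^-1
    (51.7 umol L^-1 mmHg^-1 in molar form).  Strictly decreasing in
    temperature.
    """
    t_kelvin = _check_temperature(temperature)
    mol_per_ml_per_mmhg = MMHG_IN_PA / (GAS_CONSTANT * t_kelvin) * 1e-6
    return mol_per_ml_per_mmhg * STPD_MOLAR_VOLUME


def molar_gas_capacitance(temperature: float = BODY_TEMPERATURE) -> float:
    """beta_g in molar form, umol L^-1 mmHg^-1 (51.7 at 37 C)."""
    t_kelvin = _check_temperature(temperature)
    return MMHG_IN_PA / (GAS_CONSTANT * t_kelvin) * 1e3


def saturated_water_vapour_pressure(temperature: float = BODY_TEMPERATURE) -> float:
    """Saturated water vapour pressure in mmHg (Buck equation; ~47 at 37 C)."""
    t = temperature
    hpa = 6.1121 * math.exp((18.678 - t / 234.5) * t / (257.14 + t))
    return hpa * 0.750062


def stpd_ventilation_factor(temperature: float = BODY_TEMPERATURE) -> float:
    """Factor converting a minute ventilation at body conditions to STPD flow.

    Ventilation is specified at body temperature, ambient pressure, saturated
    with water (BTPS).  The gas-phase transport terms of the model are written
    in mL STPD, so the convective gas flow is the BTPS ventilation scaled by
    (273.15/T_K) * ((P_B - P_H2O)/P_B); ~0.826 at 37 C.
    """
    t_kelvin = _check_temperature(temperature)
    p_h2o = saturated_water_vapour_pressure(temperature)
    return (ZERO_CELSIUS / t_kelvin) * ((BAROMETRIC_PRESSURE - p_h2o) / BAROMETRIC_PRESSURE)


def percent_to_mmhg(percent: float, barometric: float = BAROMETRIC_PRESSURE) -> float:
    """Convert a vaporizer setting in vol% to a partial pressure in mmHg.

    Convenience only (5% -> 38 mmHg at 760 mmHg); scenario inspired pressures
    are always specified directly in mmHg.
    """
    return percent / 100.0 * barometric


def mmhg_to_percent(pressure: float, barometric: float = BAROMETRIC_PRESSURE) -> float:
    return pressure / barometric * 100.0


class _Serializable:
    """Flat key-value (de)serialization shared by the parameter dataclasses."""

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.to_dict() if isinstance(v, _Serializable) else v
        return out

    @classmethod
    def from_dict(cls, data: dict):
        kwargs = dict(data)
        for f in fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], dict):
                sub = f.type if isinstance(f.type, type) else _NESTED.get(f.name)
                if sub is not None:
                    kwargs[f.name] = sub.from_dict(kwargs[f.name])
        return cls(**kwargs)


@dataclass(frozen=True)
class Agent(_Serializable):
    """An inhaled anaesthetic, characterised by its capacitance coefficients.

    beta_b and beta_T are the blood and (lumped) tissue capacitance
    coefficients in mL_STPD mL^-1 mmHg^-1.  Dividing by the gas capacitance
    coefficient gives the dimensionless blood-gas and tissue-gas partition
    coefficients (lambda_b ~2.4 for halothane, ~1.3 for isoflurane, ~0.64 for
    sevoflurane at 37 C).
    """

    name: str
    beta_b: float
    beta_T: float

    def __post_init__(self) -> None:
        if not (self.beta_b > 0 and self.beta_T > 0):
            raise ValueError("capacitance coefficients must be positive")


@dataclass(frozen=True)
class GasPhase(_Serializable):
    """Gas phase at a given temperature; beta_g derived from the ideal-gas law."""

    temperature: float = BODY_TEMPERATURE
    beta_g: float = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.beta_g is None:
            object.__setattr__(self, "beta_g", gas_capacitance(self.temperature))

    def to_dict(self) -> dict:
        return {"temperature": self.temperature}


def partition_coefficient(agent: Agent, gas: GasPhase) -> tuple[float, float]:
    """Blood-gas and tissue-gas partition coefficients (lambda_b, lambda_T)."""
    return agent.beta_b / gas.beta_g, agent.beta_T / gas.beta_g


def agent_from_partition(
    name: str, lambda_b: float, lambda_T: float, gas: GasPhase
) -> Agent:
    """Build an Agent from partition coefficients (inverse of partition_coefficient)."""
    if not (lambda_b > 0 and lambda_T > 0):
        raise ValueError("partition coefficients must be positive")
    return Agent(name, lambda_b * gas.beta_g, lambda_T * gas.beta_g)


@dataclass(frozen=True)
class CompartmentVolumes(_Serializable):
    """Blood, tissue and capillary pool volumes (mL) of the circulation.

    T tissue; CT tissue capillary; CL lung capillary; PV pulmonary vein;
    PA pulmonary artery; SA systemic artery; SV systemic vein; RV/LV the
    ventricular pools.
    """

    T: float
    CT: float
    CL: float
    PV: float
    PA: float
    SA: float
    SV: float
    RV: float
    LV: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if not getattr(self, f.name) > 0:
                raise ValueError(f"volume {f.name} must be positive")


_SHUNT_MODES = ("reciprocal", "maintained_systemic")


@dataclass(frozen=True)
class ShuntSpec(_Serializable):
    """Cardiac shunt fractions and the flow convention used to resolve them.

    s_RL is the fraction of systemic venous return that bypasses the lungs and
    re-enters the systemic arterial circulation; s_LR the fraction of
    pulmonary venous return recirculated to the lungs.  Bidirectional shunts
    (both nonzero) are allowed.  ``mode`` selects how cardiac output is
    redistributed (see flows.derive_flows).
    """

    s_RL: float = 0.0
    s_LR: float = 0.0
    mode: str = "reciprocal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_RL < 1.0 and 0.0 <= self.s_LR < 1.0):
            raise ValueError("shunt fractions must lie in [0, 1)")
        if self.mode not in _SHUNT_MODES:
            raise ValueError(f"mode must be one of {_SHUNT_MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class CirculationParams(_Serializable):
    """Cardiorespiratory parameters of the (1-kg reference) animal.

    Q_tot: cardiac output, mL min^-1; V_dot_L: minute ventilation at body
    conditions, mL min^-1; L: lung gas volume, mL.
    """

    Q_tot: float
    V_dot_L: float
    L: float
    volumes: CompartmentVolumes
    shunt: ShuntSpec = field(default_factory=ShuntSpec)

    def __post_init__(self) -> None:
        if not self.Q_tot > 0:
            raise ValueError("Q_tot must be positive")
        if self.V_dot_L < 0:
            raise ValueError("V_dot_L must be non-negative")
        if not self.L > 0:
            raise ValueError("lung volume must be positive")


@dataclass(frozen=True)
class FlowSolution(_Serializable):
    """Resolved circulatory flows (mL min^-1) satisfying node conservation.

    Invariants: Q_RL = s_RL*Q_sys, Q_LR = s_LR*Q_pul, and the arterial node
    balances (1-s_LR)*Q_pul + Q_RL = Q_sys and (1-s_RL)*Q_sys + Q_LR = Q_pul.
    """

    Q_sys: float
    Q_pul: float
    Q_RL: float
    Q_LR: float


_NESTED = {"volumes": CompartmentVolumes, "shunt": ShuntSpec}
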