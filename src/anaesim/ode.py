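"""Mass-balance ODE system for the ten-pool circulation (eight pressure states).

Each compartment is a uniform, well-stirred pool exchanging anaesthetic by
convection only: there is no diffusion limitation at the lung or tissue, no
ventilation-perfusion mismatch, no metabolism, and the only exchange with the
environment is through ventilation of the lung.  Blood leaving the lung is
equilibrated at the lung gas partial pressure and blood leaving the tissue at
the tissue partial pressure.  The lung and tissue capillary pools are lumped
into the lung and tissue stores respectively (no diffusion limitation makes
them isobaric with their hosts).

The state vector is ordered (L, PV, LV, SA, T, SV, RV, PA):
lung gas, pulmonary vein, left-ventricle pool, systemic artery, tissue
(with its capillary bed), systemic vein, right-ventricle pool, pulmonary
artery.  All states are partial pressures in mmHg.

Writing C_i for the effective capacities (mL_STPD mmHg^-1) and F for the
resolved flows, the system is linear: C_i dP_i/dt = (convective fluxes), with
right-to-left admixture at the systemic arterial node and left-to-right
recirculation at the pulmonary arterial node.  Summing all equations
telescopes to d(content)/dt = V_g*(P_I - P_L), with V_g the STPD-equivalent
ventilation conductance — the conservation audit used by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flows import derive_flows
from .physiology import Agent, CirculationParams, FlowSolution, GasPhase, stpd_ventilation_factor

__all__ = [
    "STATE_COMPARTMENTS",
    "COMPARTMENT_NAMES",
    "EffectiveCapacities",
    "LinearOdeSystem",
    "assemble_system",
    "total_content",
]

#: Fixed state ordering of the model (documented for reproducibility).
STATE_COMPARTMENTS = ("L", "PV", "LV", "SA", "T", "SV", "RV", "PA")

COMPARTMENT_NAMES = {
    "L": "lung",
    "PV": "pulmonary_vein",
    "LV": "left_ventricle",
    "SA": "systemic_artery",
    "T": "tissue",
    "SV": "systemic_vein",
    "RV": "right_ventricle",
    "PA": "pulmonary_artery",
}

_IDX = {code: i for i, code in enumerate(STATE_COMPARTMENTS)}


def compartment_index(compartment: str) -> int:
    """Index of a compartment by short code or long name."""
    code = compartment if compartment in _IDX else _LONG_TO_CODE.get(compartment)
    if code is None:
        raise KeyError(
            f"unknown compartment {compartment!r}; expected one of "
            f"{STATE_COMPARTMENTS} (or long names {tuple(COMPARTMENT_NAMES.values())})"
        )
    return _IDX[code]


_LONG_TO_CODE = {v: k for k, v in COMPARTMENT_NAMES.items()}


@dataclass(frozen=True)
class EffectiveCapacities:
    """Anaesthetic stores per compartment, mL_STPD mmHg^-1.

    The lung store combines the gas space with its capillary blood
    (C_L = L*beta_g + V_CL*beta_b); the tissue store combines tissue with its
    capillary bed (C_T = V_T*beta_T + V_CT*beta_b); pure blood pools are
    V_i*beta_b.
    """

    C_L: float
    C_PV: float
    C_LV: float
    C_SA: float
    C_T: float
    C_SV: float
    C_RV: float
    C_PA: float

    @classmethod
    def compute(
        cls, agent: Agent, gas: GasPhase, params: CirculationParams
    ) -> "EffectiveCapacities":
        v = params.volumes
        bb = agent.beta_b
        return cls(
            C_L=params.L * gas.beta_g + v.CL * bb,
            C_PV=v.PV * bb,
            C_LV=v.LV * bb,
            C_SA=v.SA * bb,
            C_T=v.T * agent.beta_T + v.CT * bb,
            C_SV=v.SV * bb,
            C_RV=v.RV * bb,
            C_PA=v.PA * bb,
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.C_L, self.C_PV, self.C_LV, self.C_SA,
             self.C_T, self.C_SV, self.C_RV, self.C_PA]
        )


@dataclass(frozen=True)
class LinearOdeSystem:
    """dP/dt = A P + b, with capacities and flows retained for audits."""

    A: np.ndarray
    b: np.ndarray
    capacities: EffectiveCapacities
    flows: FlowSolution
    P_I: float
    ventilation_conductance: float  # V_g = effective ventilation * beta_g

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:  # noqa: ARG002
        return self.A @ y + self.b

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:  # noqa: ARG002
        return self.A

    def lung_flux(self, p_lung: np.ndarray | float) -> np.ndarray | float:
        """Net uptake through the lung, mL_STPD min^-1, at lung pressure(s)."""
        return self.ventilation_conductance * (self.P_I - p_lung)


def assemble_system(
    agent: Agent,
    gas: GasPhase,
    params: CirculationParams,
    P_I: float,
    *,
    ventilation_stpd: bool = True,
) -> LinearOdeSystem:
    """Build the linear mass-balance system for a constant inspired pressure.

    ``ventilation_stpd`` applies the BTPS->STPD conversion to the minute
    ventilation before forming the gas transport term (the model's default
    convention; see docs/methods.md).
    """
    if P_I < 0:
        raise ValueError("inspired partial pressure must be non-negative")
    caps = EffectiveCapacities.compute(agent, gas, params)
    flows = derive_flows(params)
    bb = agent.beta_b
    s_rl, s_lr = params.shunt.s_RL, params.shunt.s_LR
    q_sys, q_pul = flows.Q_sys, flows.Q_pul

    vent = params.V_dot_L * (
        stpd_ventilation_factor(gas.temperature) if ventilation_stpd else 1.0
    )
    v_g = vent * gas.beta_g

    n = len(STATE_COMPARTMENTS)
    A = np.zeros((n, n))
    b = np.zeros(n)
    iL, iPV, iLV, iSA, iT, iSV, iRV, iPA = range(n)

    # lung: ventilation exchange + equilibrated pulmonary blood throughput
    A[iL, iL] = -(v_g + q_pul * bb)
    A[iL, iPA] = q_pul * bb
    b[iL] = v_g * P_I
    # pulmonary vein and left-ventricle pool: series transport at Q_pul
    A[iPV, iL] = q_pul * bb
    A[iPV, iPV] = -q_pul * bb
    A[iLV, iPV] = q_pul * bb
    A[iLV, iLV] = -q_pul * bb
    # systemic artery: left-ventricular outflow plus right-to-left admixture
    A[iSA, iLV] = (1.0 - s_lr) * q_pul * bb
    A[iSA, iRV] = s_rl * q_sys * bb
    A[iSA, iSA] = -q_sys * bb
    # tissue (with capillary bed): perfusion at Q_sys, outflow at P_T
    A[iT, iSA] = q_sys * bb
    A[iT, iT] = -q_sys * bb
    # systemic vein and right-ventricle pool
    A[iSV, iT] = q_sys * bb
    A[iSV, iSV] = -q_sys * bb
    A[iRV, iSV] = q_sys * bb
    A[iRV, iRV] = -q_sys * bb
    # pulmonary artery: right-ventricular outflow plus left-to-right recirculation
    A[iPA, iRV] = (1.0 - s_rl) * q_sys * bb
    A[iPA, iLV] = s_lr * q_pul * bb
    A[iPA, iPA] = -q_pul * bb

    c = caps.as_array()
    return LinearOdeSystem(
        A=A / c[:, None],
        b=b / c,
        capacities=caps,
        flows=flows,
        P_I=P_I,
        ventilation_conductance=v_g,
    )


def total_content(state: np.ndarray, caps: EffectiveCapacities) -> float | np.ndarray:
    """Total anaesthetic content Σ C_i P_i, mL_STPD.

    ``state`` may be a single state vector or an (8, n) trajectory.
    """
    c = caps.as_array()
    state = np.asarray(state)
    if state.ndim == 1:
        return float(c @ state)
    return c @ state
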