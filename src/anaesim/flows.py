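"""Resolve shunt fractions and cardiac output into conserved circulatory flows.

With an intracardiac shunt the systemic and pulmonary flows differ.  Two
conventions are provided for how total cardiac output redistributes:

``reciprocal`` (default)
    Total ventricular output is conserved at its no-shunt value,
    Q_sys + Q_pul = 2*Q_tot: a right-to-left shunt that lowers pulmonary flow
    raises systemic flow reciprocally.

``maintained_systemic``
    Systemic flow is held at Q_tot while pulmonary flow falls, so total
    ventricular output is reduced — the situation argued for chelonians,
    where right-to-left shunting accompanies a lower total cardiac output.

Both reduce to the series circuit Q_sys = Q_pul = Q_tot at zero shunt, and in
both Q_pul = Q_sys*(1-s_RL)/(1-s_LR) so that the ventricular nodes balance.
"""

from __future__ import annotations

from .physiology import CirculationParams, FlowSolution, ShuntSpec

__all__ = [
    "DegenerateCirculationError",
    "derive_flows",
    "pulmonary_bypass_to_srl",
    "srl_to_pulmonary_bypass",
]


class DegenerateCirculationError(ValueError):
    """The shunt specification leaves no physically meaningful circulation."""


def derive_flows(params: CirculationParams) -> FlowSolution:
    """Resolve (Q_tot, shunt spec) into systemic, pulmonary and shunt flows."""
    shunt = params.shunt
    s_rl, s_lr = shunt.s_RL, shunt.s_LR
    if s_lr >= 1.0:
        raise DegenerateCirculationError(
            "s_LR = 1 recirculates all pulmonary venous blood (infinite recirculation)"
        )
    if s_rl >= 1.0 and s_lr >= 1.0:
        raise DegenerateCirculationError("s_RL = s_LR = 1 is a closed loop")

    if shunt.mode == "maintained_systemic":
        q_sys = params.Q_tot
    else:  # reciprocal: Q_sys + Q_pul = 2 Q_tot
        q_sys = 2.0 * params.Q_tot * (1.0 - s_lr) / ((1.0 - s_lr) + (1.0 - s_rl))
    q_pul = q_sys * (1.0 - s_rl) / (1.0 - s_lr)
    return FlowSolution(
        Q_sys=q_sys, Q_pul=q_pul, Q_RL=s_rl * q_sys, Q_LR=s_lr * q_pul
    )


def pulmonary_bypass_to_srl(p: float) -> float:
    """Map a fractional pulmonary-flow reduction to the equivalent s_RL.

    The shunt severity axis used by the reptilian scenarios expresses "a shunt
    of p" as pulmonary flow reduced to (1-p) of cardiac output, with the
    balance diverted systemically: Q_pul = (1-p)*Q_tot, Q_sys = (1+p)*Q_tot
    under the reciprocal convention.  In the node-balance parameterization
    this is s_RL = 2p/(1+p) (0.5 -> 2/3; 0.9 -> 0.947).
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("pulmonary bypass fraction must lie in [0, 1)")
    return 2.0 * p / (1.0 + p)


def srl_to_pulmonary_bypass(s_rl: float) -> float:
    """Inverse of pulmonary_bypass_to_srl: p = s_RL/(2 - s_RL)."""
    if not 0.0 <= s_rl < 1.0:
        raise ValueError("s_RL must lie in [0, 1)")
    return s_rl / (2.0 - s_rl)
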