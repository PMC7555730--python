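import numpy as np
import pytest

from anaesim import (
    AGENTS,
    CirculationParams,
    CompartmentVolumes,
    GasPhase,
    ShuntSpec,
)

STANDARD_VOLUMES = CompartmentVolumes(
    T=600, CT=0.15, CL=0.15, PV=12, PA=7.5, SA=15, SV=37.5, RV=0.75, LV=0.75
)


@pytest.fixture(scope="session")
def gas37() -> GasPhase:
    return GasPhase(37.0)


@pytest.fixture(scope="session")
def volumes() -> CompartmentVolumes:
    return STANDARD_VOLUMES


@pytest.fixture(scope="session")
def rabbit_params(volumes) -> CirculationParams:
    return CirculationParams(Q_tot=175, V_dot_L=500, L=75, volumes=volumes)


@pytest.fixture(scope="session")
def reptile_params(volumes) -> CirculationParams:
    return CirculationParams(Q_tot=60, V_dot_L=30, L=150, volumes=volumes)


@pytest.fixture(scope="session")
def shunt_base_params(volumes) -> CirculationParams:
    """The reptilian-type shunting circulation (no shunt baseline)."""
    return CirculationParams(Q_tot=100, V_dot_L=100, L=150, volumes=volumes)


@pytest.fixture(scope="session")
def isoflurane():
    return AGENTS["isoflurane"]


@pytest.fixture(scope="session")
def sevoflurane():
    return AGENTS["sevoflurane"]


@pytest.fixture(scope="session")
def halothane():
    return AGENTS["halothane"]


def with_shunt(params: CirculationParams, s_RL=0.0, s_LR=0.0, mode="reciprocal"):
    from dataclasses import replace

    return replace(params, shunt=ShuntSpec(s_RL=s_RL, s_LR=s_LR, mode=mode))


def euler_trajectory(system, y0, t_end, dt):
    """Fixed-step explicit Euler oracle, independent of scipy's integrators."""
    n = int(round(t_end / dt))
    y = np.array(y0, dtype=float)
    a, b = system.A, system.b
    for _ in range(n):
        y = y + dt * (a @ y + b)
    return y
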