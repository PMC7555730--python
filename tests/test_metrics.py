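"""Equilibration metrics: crossing detection, references, crossover search."""

import numpy as np
import pytest

from anaesim import (
    AGENTS,
    Agent,
    GasPhase,
    Protocol,
    TimeSeries,
    crossover_shunt,
    equilibration_fraction,
    simulate,
    t90,
    time_to_pressure,
)
from conftest import with_shunt


def synthetic_series(fn, t_end=10.0, grid=0.01, P_I=35.0):
    """A TimeSeries whose eight traces all follow the closed form fn(t)."""
    t = np.arange(0.0, t_end + grid / 2, grid)
    trace = fn(t)
    return TimeSeries(
        t,
        np.tile(trace, (8, 1)),
        {"protocol": {"phases": [[t_end, P_I]], "output_grid": grid}},
    )


class TestT90:
    def test_exponential_closed_form(self):
        """P = 35(1 - e^-t): t90 against the 35-mmHg asymptote is ln 10."""
        ts = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)))
        res = t90(ts, "SA", reference=35.0)
        assert res.time == pytest.approx(np.log(10.0), abs=5e-3)
        assert res.reached

    def test_inspired_reference_from_metadata(self):
        ts = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)))
        assert t90(ts, "SA").reference_pressure == 35.0

    def test_capped_series_not_reached(self):
        ts = synthetic_series(lambda t: np.minimum(30.0, 35.0 * (1.0 - np.exp(-t))))
        res = t90(ts, "SA", reference=35.0)
        assert res.time is None and not res.reached

    def test_end_of_exposure_reference(self):
        ts = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)), t_end=5.0)
        res = t90(ts, "SA", reference="end_of_exposure")
        plateau = 35.0 * (1.0 - np.exp(-5.0))
        assert res.reference_pressure == pytest.approx(plateau, rel=1e-6)
        assert res.time == pytest.approx(-np.log(1.0 - 0.9 * plateau / 35.0), abs=5e-3)

    def test_interpolation_is_grid_insensitive(self):
        fine = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)), grid=0.001)
        coarse = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)), grid=0.05)
        tf = t90(fine, "SA", reference=35.0).time
        tc = t90(coarse, "SA", reference=35.0).time
        assert abs(tf - tc) < 0.025  # within half the coarse grid step

    def test_empty_series_rejected(self):
        ts = synthetic_series(lambda t: t)
        ts.times = ts.times[:0]
        ts.pressures = ts.pressures[:, :0]
        with pytest.raises(ValueError):
            t90(ts, "SA", reference=35.0)


class TestTimeToPressure:
    def test_zero_threshold_is_immediate(self):
        ts = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)))
        assert time_to_pressure(ts, "SA", 0.0) == 0.0

    def test_unreachable_threshold(self):
        ts = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)))
        assert time_to_pressure(ts, "SA", 40.0) is None

    def test_interpolated_crossing(self):
        ts = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)))
        # P = 17.5 at t = ln 2
        assert time_to_pressure(ts, "SA", 17.5) == pytest.approx(np.log(2.0), abs=5e-3)

    def test_surgical_threshold_reached_quickly_in_rabbit(self, gas37, rabbit_params):
        """High-inspired sevoflurane induction reaches 28 mmHg in well under a minute."""
        ts = simulate(AGENTS["sevoflurane"], gas37, rabbit_params, Protocol.washin(5.0, 53.5))
        t_mac = time_to_pressure(ts, "SA", 28.0)
        assert t_mac is not None and t_mac < 0.5


class TestEquilibrationFraction:
    def test_fraction_at_t90_time_is_ninety_percent(self):
        ts = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)))
        res = t90(ts, "SA", reference=35.0)
        frac = equilibration_fraction(ts, "SA", res.time, reference=35.0)
        assert frac == pytest.approx(0.9, abs=1e-3)

    def test_zero_at_start(self):
        ts = synthetic_series(lambda t: 35.0 * (1.0 - np.exp(-t)))
        assert equilibration_fraction(ts, "SA", 0.0, reference=35.0) == 0.0

    def test_outside_horizon_rejected(self):
        ts = synthetic_series(lambda t: t, t_end=1.0)
        with pytest.raises(ValueError):
            equilibration_fraction(ts, "SA", 2.0, reference=35.0)

    def test_low_cardiac_output_faster_early_slower_late(self, gas37):
        """Early arterial rise is faster at low cardiac output; the ordering
        reverses approaching full equilibration."""
        from anaesim import load_preset

        iso = AGENTS["isoflurane"]
        runs = {}
        for pid in ("fig4c_q50", "fig4c_q300"):
            sc = load_preset(pid)
            runs[pid] = simulate(iso, gas37, sc.params, Protocol.washin(400.0, 30.0, 0.02))
        early_lo = equilibration_fraction(runs["fig4c_q50"], "SA", 5.0)
        early_hi = equilibration_fraction(runs["fig4c_q300"], "SA", 5.0)
        assert early_lo > early_hi
        t90_lo = t90(runs["fig4c_q50"], "SA").time
        t90_hi = t90(runs["fig4c_q300"], "SA").time
        assert t90_hi < t90_lo


class TestCrossoverShunt:
    def test_identical_agents_rejected(self, gas37, shunt_base_params):
        iso = AGENTS["isoflurane"]
        clone = Agent("copy", iso.beta_b, iso.beta_T)
        with pytest.raises(ValueError):
            crossover_shunt(iso, clone, gas37, shunt_base_params, [0.0, 0.5])

    def test_less_soluble_agent_faster_without_shunt(self, gas37, shunt_base_params):
        """Zero-shunt ordering: smaller beta_b equilibrates faster."""
        results = {}
        for name in ("halothane", "isoflurane", "sevoflurane"):
            ts = simulate(AGENTS[name], gas37, shunt_base_params,
                          Protocol.washin(600.0, 30.0, 0.02))
            results[name] = t90(ts, "SA").time
        assert results["sevoflurane"] < results["isoflurane"] < results["halothane"]

    def test_crossover_found_and_beyond_configured_grid_start(self, gas37, shunt_base_params):
        s = crossover_shunt(
            AGENTS["isoflurane"], AGENTS["sevoflurane"], gas37, shunt_base_params,
            np.linspace(0.0, 0.96, 9), P_I=30.0, output_grid=0.05, refine_tol=0.01,
        )
        assert s is not None and 0.8 < s < 1.0

    def test_no_crossover_within_truncated_grid(self, gas37, shunt_base_params):
        s = crossover_shunt(
            AGENTS["isoflurane"], AGENTS["sevoflurane"], gas37, shunt_base_params,
            [0.0, 0.2, 0.4], P_I=30.0, output_grid=0.05,
        )
        assert s is None


class TestMonotonicityProperties:
    def test_t90_decreasing_in_ventilation(self, gas37, shunt_base_params):
        from dataclasses import replace

        iso = AGENTS["isoflurane"]
        values = []
        for v in (10.0, 50.0, 150.0, 500.0, 1000.0):
            p = replace(shunt_base_params, V_dot_L=v)
            ts = simulate(iso, gas37, p, Protocol.washin(4000.0, 30.0, 0.05))
            values.append(t90(ts, "SA").time)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_t90_increasing_in_shunt(self, gas37, shunt_base_params):
        iso = AGENTS["isoflurane"]
        values = []
        for s in (0.0, 0.3, 0.6, 0.9):
            p = with_shunt(shunt_base_params, s_RL=s)
            ts = simulate(iso, gas37, p, Protocol.washin(4000.0, 30.0, 0.05))
            values.append(t90(ts, "SA").time)
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_t90_increasing_in_solubility_along_constant_ratio(self, gas37, shunt_base_params):
        from anaesim.scenarios import ISOFLURANE_TISSUE_BLOOD_RATIO as RATIO

        values = []
        for bb in (2e-4, 8e-4, 2e-3, 4e-3):
            agent = Agent(f"b{bb}", beta_b=bb, beta_T=bb * RATIO)
            ts = simulate(agent, gas37, shunt_base_params, Protocol.washin(4000.0, 30.0, 0.05))
            values.append(t90(ts, "SA").time)
        assert all(a < b for a, b in zip(values, values[1:]))
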