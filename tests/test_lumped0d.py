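from dataclasses import replace

import numpy as np
import pytest

from graftflow import fixtures as fx
from graftflow.io_core import MMHG_TO_PA
from graftflow.lumped0d import (
    CalibrationError,
    FixedPressure,
    Inflow,
    Network0D,
    NetworkError,
    Segment0D,
    WK3Params,
    calibrate_wk3,
    fit_quadratic_resistance,
    network_from_dict,
    network_to_dict,
    segment_inertance,
    simulate_network,
)
from graftflow.waveforms import Waveform


def constant_inflow(q0, T=1.0, n=16):
    t = T * np.arange(n) / n
    return Waveform(t, np.full(n, q0), T)


def single_segment_net(a=0.0, b=1e8, L=0.0, termination=None):
    seg = Segment0D("s", "IN", "OUT", a=a, b=b, L=L)
    term = termination if termination is not None else FixedPressure(1000.0)
    return Network0D(["IN", "OUT"], [seg], {"IN": Inflow(), "OUT": term})


class TestInertance:
    def test_large_artery_formula(self):
        # (4/3) * 1056 * 0.1 / 1e-5
        assert segment_inertance(0.1, 1e-5, 1056.0) == pytest.approx(1.408e7, rel=1e-12)

    def test_zero_length_gives_zero(self):
        assert segment_inertance(0.0, 1e-5, 1056.0) == 0.0

    def test_inverse_proportionality_to_area(self):
        assert segment_inertance(0.1, 2e-5, 1056.0) == pytest.approx(
            segment_inertance(0.1, 1e-5, 1056.0) / 2
        )

    def test_nonpositive_area_rejected(self):
        with pytest.raises(NetworkError):
            segment_inertance(0.1, 0.0, 1056.0)


class TestQuadraticFit:
    def test_exact_recovery_on_noiseless_quadratic(self):
        q = np.array([1.0, 2.0, 3.0])
        a, b, res = fit_quadratic_resistance(q, 2 * q**2 + 3 * q)
        assert a == pytest.approx(2.0, abs=1e-9)
        assert b == pytest.approx(3.0, abs=1e-9)
        assert res < 1e-9

    def test_linear_data(self):
        q = np.array([0.5, 1.0, 2.0])
        a, b, _ = fit_quadratic_resistance(q, 5 * q)
        assert a == pytest.approx(0.0, abs=1e-9)
        assert b == pytest.approx(5.0, abs=1e-9)

    def test_zero_pressure_drop(self):
        a, b, _ = fit_quadratic_resistance([1.0, 2.0], [0.0, 0.0])
        assert a == 0.0 and b == 0.0

    def test_identical_flows_rejected(self):
        with pytest.raises(NetworkError, match="rank"):
            fit_quadratic_resistance([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestSimulate:
    def test_ohmic_steady_state_exact(self):
        B, Q0, PV = 2e8, 1e-5, 1000.0
        net = single_segment_net(b=B, termination=FixedPressure(PV))
        sol = simulate_network(net, constant_inflow(Q0), dt=0.01, n_cycles=2)
        assert np.allclose(sol.pressures["IN"], PV + B * Q0, rtol=1e-10)
        assert np.allclose(sol.flows["s"], Q0, rtol=1e-10)

    def test_wk3_steady_state(self):
        Q0 = 1e-5
        wk3 = WK3Params(r_p=1e9, r_d=2e9, c=5e-11, p_ref=500.0)  # tau = 0.1 s
        net = single_segment_net(b=0.0, termination=wk3)
        sol = simulate_network(net, constant_inflow(Q0), dt=0.002, n_cycles=3)
        expected = 500.0 + (1e9 + 2e9) * Q0
        assert sol.pressures["OUT"][-1] == pytest.approx(expected, rel=1e-6)

    def test_wk3_step_response_time_constant(self):
        # constant inflow from rest: boundary pressure relaxes to its steady
        # value exponentially with tau = R_d * C
        Q0, rd, c = 1e-5, 2e9, 5e-11  # tau = 0.1 s
        wk3 = WK3Params(r_p=1e9, r_d=rd, c=c, p_ref=0.0)
        net = single_segment_net(b=0.0, termination=wk3)
        dt = 2.5e-4
        sol = simulate_network(net, constant_inflow(Q0), dt=dt, n_cycles=1)
        p = sol.pressures["OUT"]
        p_inf = rd * Q0 + 1e9 * Q0
        # log-linear fit of the decaying tail over [0.5, 2.5] tau
        mask = (sol.times > 0.05) & (sol.times < 0.25)
        y = np.log(p_inf - p[mask])
        slope = np.polyfit(sol.times[mask], y, 1)[0]
        assert -1.0 / slope == pytest.approx(rd * c, rel=0.005)

    def test_junction_mass_conservation(self):
        net = fx.toy_avg_network()
        sol = simulate_network(net, fx.parametric_inflow(), dt=1 / 200, n_cycles=3)
        assert sol.mass_residual < 1e-10

    def test_outlet_fractions_sum_to_one(self):
        net = fx.toy_avg_network()
        sol = simulate_network(net, fx.parametric_inflow(), dt=1 / 200, n_cycles=6)
        assert sum(sol.outlet_mean_fractions.values()) == pytest.approx(1.0, abs=1e-4)

    def test_dt_refinement_changes_systolic_below_threshold(self):
        net = fx.toy_avg_network()
        inflow = fx.parametric_inflow()
        p1 = simulate_network(net, inflow, dt=1 / 250, n_cycles=5).systolic_inlet_pressure
        p2 = simulate_network(net, inflow, dt=1 / 500, n_cycles=5).systolic_inlet_pressure
        assert abs(p2 - p1) / p1 < 0.002

    def test_linear_network_scales_with_inflow(self):
        net = fx.toy_avg_network()
        lin_segments = [replace(s, a=0.0, L=0.0) for s in net.segments]
        terms = {
            n: (FixedPressure(0.0) if isinstance(t, FixedPressure) else t)
            for n, t in net.terminations.items()
        }
        for n in net.wk3_nodes:
            terms[n] = replace(terms[n], p_ref=0.0)
        lin = Network0D(list(net.nodes), lin_segments, terms)
        w1 = fx.parametric_inflow()
        w2 = Waveform(w1.times, 2.0 * w1.values, w1.period)
        s1 = simulate_network(lin, w1, dt=1 / 200, n_cycles=6)
        s2 = simulate_network(lin, w2, dt=1 / 200, n_cycles=6)
        for node in lin.nodes:
            assert np.allclose(s2.pressures[node], 2.0 * s1.pressures[node], rtol=1e-5)

    def test_power_balance_in_periodic_state(self):
        # with zero reference/venous pressures, cycle-mean inflow power
        # equals the summed resistive dissipation once periodic
        net = fx.toy_avg_network(venous_pressure=0.0)
        terms = {
            n: (replace(t, p_ref=0.0) if isinstance(t, WK3Params) else t)
            for n, t in net.terminations.items()
        }
        net = Network0D(list(net.nodes), list(net.segments), terms)
        inflow = fx.parametric_inflow()
        sol = simulate_network(net, inflow, dt=1 / 400, n_cycles=10)
        T = inflow.period
        t = sol.times
        p_in = np.trapezoid(sol.pressures["IN"] * sol.inflow_values, t) / T
        dissipated = 0.0
        for s in net.segments:
            q = sol.flows[s.name]
            dissipated += np.trapezoid(s.a * np.abs(q) * q * q + s.b * q * q, t) / T
        for n in net.wk3_nodes:
            wk = net.terminations[n]
            q = sol.outlet_flows[n]
            pc = sol.pressures[n] - wk.r_p * q
            dissipated += np.trapezoid(wk.r_p * q * q + pc**2 / wk.r_d, t) / T
        assert p_in >= dissipated * 0.99
        assert p_in == pytest.approx(dissipated, rel=0.01)

    def test_invalid_topology_rejected(self):
        seg = Segment0D("s", "IN", "OUT", b=1.0)
        with pytest.raises(NetworkError, match="termination"):
            Network0D(["IN", "OUT"], [seg], {"IN": Inflow()})
        with pytest.raises(NetworkError, match="inflow"):
            Network0D(["IN", "OUT"], [seg], {"OUT": FixedPressure(0.0)})


class TestCalibration:
    def test_forward_inverse_consistency(self):
        # calibrate against targets produced by a known parameter set; the
        # achieved targets must be recovered within the stated tolerances
        net = fx.toy_avg_network()
        inflow = fx.parametric_inflow()
        truth = WK3Params(r_p=1.6e9, r_d=2.4e9, c=1.3e-10, p_ref=8 * MMHG_TO_PA)
        fwd = simulate_network(net.with_wk3(truth), inflow, dt=1 / 250, n_cycles=6)
        sys_t = fwd.systolic_inlet_pressure
        split_t = fwd.arterial_split(net)
        params = calibrate_wk3(net, inflow, sys_t, split_t, band=0.05)
        chk = simulate_network(net.with_wk3(params), inflow, dt=1 / 250, n_cycles=6)
        assert chk.systolic_inlet_pressure == pytest.approx(sys_t, rel=0.01)
        assert chk.arterial_split(net) == pytest.approx(split_t, abs=0.05)

    def test_infeasible_split_raises_with_achieved_values(self):
        net = fx.toy_avg_network()
        inflow = fx.parametric_inflow()
        with pytest.raises(CalibrationError) as exc:
            calibrate_wk3(
                net, inflow, 110 * MMHG_TO_PA, split_target=1.0, band=0.05,
                dt=1 / 100, n_cycles=3,
            )
        assert exc.value.achieved_split is not None
        assert exc.value.achieved_split < 0.95

    def test_calibration_is_deterministic(self):
        net = fx.toy_avg_network()
        inflow = fx.parametric_inflow()
        p1 = calibrate_wk3(net, inflow, 110 * MMHG_TO_PA, 0.27, band=0.05, dt=1 / 150, n_cycles=4)
        p2 = calibrate_wk3(net, inflow, 110 * MMHG_TO_PA, 0.27, band=0.05, dt=1 / 150, n_cycles=4)
        assert p1 == p2


class TestToyNetwork:
    def test_topology_counts(self):
        net = fx.toy_avg_network()
        assert len(net.segments) == 6
        assert len(net.wk3_nodes) == 3
        assert len(net.sink_nodes) == 1
        assert net.inflow_node == "IN"

    def test_serialisation_roundtrip(self):
        net = fx.toy_avg_network()
        back = network_from_dict(network_to_dict(net))
        assert back.nodes == net.nodes
        assert back.segments == net.segments
        assert back.terminations == net.terminations

    def test_venous_sink_at_8_mmhg(self):
        net = fx.toy_avg_network()
        assert net.terminations["VO"].pressure == pytest.approx(8 * MMHG_TO_PA)
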