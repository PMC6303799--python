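"""1D solver physics: equilibria, steady limits, wave propagation,
junction coupling, stenosis loss and Windkessel outlet dynamics."""

import math

import numpy as np
import pytest

import pulsetrim as pt
from pulsetrim.solver import wk3_outlet_step, wkcor_outlet_step
from pulsetrim.testkit import oracle_wk_decay
from pulsetrim.units import MMHG


def constant_inflow(Q0, T=1.0, n=128):
    return pt.PeriodicWaveform(np.arange(n) * T / n, np.full(n, Q0), T)


class TestEquilibriumAndSteady:
    def test_zero_inflow_stays_at_rest(self, single_vessel):
        net = single_vessel
        net.inflow_boundary.params["waveform"] = constant_inflow(0.0)
        for b in net.boundaries:
            if not b.is_inflow:
                b.params["P_out"] = 80 * MMHG  # equilibrium with P_dia
        cfg = pt.SolverConfig(output_sites=[("v0", 0.5)], max_cycles=3)
        res = pt.run_simulation(net, cfg)
        drift = np.max(np.abs(res.waveform("v0", 0.5, "P").values - 80 * MMHG))
        assert drift < 1e-9 * MMHG

    def test_constant_inflow_reaches_series_resistance_steady_state(
        self, single_vessel
    ):
        Q0 = 70.0
        net = single_vessel
        net.inflow_boundary.params["waveform"] = constant_inflow(Q0)
        out = next(b for b in net.boundaries if not b.is_inflow)
        cfg = pt.SolverConfig(output_sites=[("v0", 0.0)], max_cycles=20)
        res = pt.run_simulation(net, cfg)
        assert res.converged
        ss = pt.solve_steady(net)
        R_v = pt.segment_viscous_resistance(
            net.segments[0], net.blood, ss.area_profile("v0")
        )
        predicted = out.params["P_out"] + (
            out.params["R1"] + out.params["R2"] + R_v
        ) * Q0
        P_in = res.waveform("v0", 0.0, "P").mean()
        assert P_in == pytest.approx(predicted, rel=0.01)


class TestWavePropagation:
    def test_small_pulse_travels_at_diastolic_wave_speed(self, blood):
        seg = pt.ArterialSegment(
            id="v", length=60.0, r_prox_dia=1.0, r_dist_dia=1.0,
            p_dia_ref=80 * MMHG,
        )
        c_d = pt.wave_speed(1.0, seg.wall_law, blood)
        T, n = 0.6, 2048
        t = np.arange(n) * T / n
        q = 5.0 * np.exp(-0.5 * ((t - 0.05) / 0.008) ** 2)
        Z_c = blood.rho * c_d / float(seg.area_d(1.0))
        net = pt.VascularNetwork(
            segments=[seg],
            topology={"in": [("v", "prox")], "out": [("v", "dist")]},
            boundaries=[
                pt.BoundaryCondition(
                    "in", "inflow_Q",
                    {"waveform": pt.PeriodicWaveform(t, q, T)},
                ),
                pt.BoundaryCondition(
                    "out", "wk3",
                    {"R1": Z_c, "C": 1e-4, "R2": 1700.0, "P_out": 80 * MMHG},
                ),
            ],
            blood=blood,
        )
        cfg = pt.SolverConfig(
            output_sites=[("v", 0.2), ("v", 0.7)], max_cycles=1
        )
        res = pt.run_simulation(net, cfg)

        def foot_time(wf):
            p = wf.values - wf.values[0]
            amp = p.max()
            idx = int(np.argmax(p > 0.1 * amp))
            frac = (0.1 * amp - p[idx - 1]) / (p[idx] - p[idx - 1])
            return wf.t[idx - 1] + frac * (wf.t[idx] - wf.t[idx - 1])

        t1 = foot_time(res.waveform("v", 0.2, "P"))
        t2 = foot_time(res.waveform("v", 0.7, "P"))
        speed = 0.5 * seg.length / (t2 - t1)
        assert speed == pytest.approx(c_d, rel=0.03)

    def test_grid_refinement_changes_pressure_below_half_percent(
        self, single_vessel
    ):
        site = [("v0", 0.5)]
        res_c = pt.run_simulation(
            single_vessel, pt.SolverConfig(dx_target=0.5, output_sites=site)
        )
        res_f = pt.run_simulation(
            single_vessel, pt.SolverConfig(dx_target=0.25, output_sites=site)
        )
        err = pt.eps_avg(
            res_f.waveform("v0", 0.5, "P"), res_c.waveform("v0", 0.5, "P")
        )
        assert err < 0.005


class TestJunctions:
    def test_symmetric_bifurcation_splits_flow_equally(self, tree_baseline):
        net, res = tree_baseline
        q0 = res.waveform("s00", 1.0, "Q").values
        q1 = res.waveform("s11", 1.0, "Q").values
        assert np.max(np.abs(q0 - q1)) <= 1e-9 * np.max(np.abs(q0))

    def test_junction_mass_defect_is_negligible(self, tree_baseline):
        _, res = tree_baseline
        assert res.max_junction_mass_defect < 1e-8

    def test_pass_through_junction_is_transparent(self, blood):
        # a straight vessel split into two identical segments behaves like
        # one: the mid-interface transmits the wave without reflection
        mk = lambda sid: pt.ArterialSegment(
            id=sid, length=8.0, r_prox_dia=0.6, r_dist_dia=0.6,
            p_dia_ref=80 * MMHG,
        )
        wave = pt.synthetic_inflow(SV=40.0)
        c_d = pt.wave_speed(0.6, pt.SYSTEMIC_WALL_LAW, blood)
        Z_c = blood.rho * c_d / float(mk("a").area_d(1.0))
        net2 = pt.VascularNetwork(
            segments=[mk("a"), mk("b")],
            topology={
                "in": [("a", "prox")], "mid": [("a", "dist"), ("b", "prox")],
                "out": [("b", "dist")],
            },
            boundaries=[
                pt.BoundaryCondition("in", "inflow_Q", {"waveform": wave}),
                pt.BoundaryCondition(
                    "out", "wk3",
                    {"R1": Z_c, "C": 2e-4, "R2": 1700.0, "P_out": 5 * MMHG},
                ),
            ],
            blood=blood,
        )
        seg1 = pt.ArterialSegment(
            id="w", length=16.0, r_prox_dia=0.6, r_dist_dia=0.6,
            p_dia_ref=80 * MMHG,
        )
        net1 = pt.VascularNetwork(
            segments=[seg1],
            topology={"in": [("w", "prox")], "out": [("w", "dist")]},
            boundaries=[
                pt.BoundaryCondition("in", "inflow_Q", {"waveform": wave}),
                pt.BoundaryCondition(
                    "out", "wk3",
                    {"R1": Z_c, "C": 2e-4, "R2": 1700.0, "P_out": 5 * MMHG},
                ),
            ],
            blood=blood,
        )
        cfg2 = pt.SolverConfig(output_sites=[("a", 0.5)])
        cfg1 = pt.SolverConfig(output_sites=[("w", 0.25)])
        r2 = pt.run_simulation(net2, cfg2)
        r1 = pt.run_simulation(net1, cfg1)
        err = pt.eps_avg(
            r1.waveform("w", 0.25, "P"), r2.waveform("a", 0.5, "P")
        )
        assert err < 0.005


class TestStenosisLoss:
    def test_hand_values(self):
        st = pt.StenosisDescriptor(
            segment_id="s", x_start=1, length_s=1, A0=1.0, As=0.5,
            K_visc=100.0, K_exp=10.0,
        )
        assert pt.stenosis_pressure_loss(0.0, st) == 0.0
        assert pt.stenosis_pressure_loss(5.0, st) == pytest.approx(750.0)

    def test_loss_opposes_flow_in_both_directions(self):
        st = pt.StenosisDescriptor(
            segment_id="s", x_start=1, length_s=1, A0=1.0, As=0.5,
            K_visc=100.0, K_exp=10.0,
        )
        for Q in np.linspace(-10, 10, 41):
            assert np.sign(pt.stenosis_pressure_loss(Q, st)) == np.sign(Q) or Q == 0


class TestWK3Outlet:
    def test_constant_flow_steady_state(self):
        R1, C, R2, P_out = 150.0, 2e-4, 1400.0, 5 * MMHG
        Q0 = 10.0
        P_c = 5 * MMHG
        dt = 1e-3
        for _ in range(30000):
            P, P_c = wk3_outlet_step(Q0, Q0, P_c, R1, C, R2, P_out, dt)
        assert P == pytest.approx(P_out + (R1 + R2) * Q0, rel=1e-6)

    def test_zero_flow_decay_matches_closed_form(self):
        R1, C, R2, P_out = 100.0, 2e-4, 1500.0, 5 * MMHG
        dt, n = 1e-4, 20000
        P_c = 100 * MMHG
        worst = 0.0
        for k in range(1, n + 1):
            _, P_c = wk3_outlet_step(0.0, 0.0, P_c, R1, C, R2, P_out, dt)
            exact = oracle_wk_decay(k * dt, 100 * MMHG, P_out, R2, C)
            worst = max(worst, abs(P_c - exact) / abs(exact))
        assert worst < 1e-4

    def test_matched_impedance_absorbs_the_pulse(self, blood):
        # R1 = Z_c: reflected wave at the outlet stays below 2% of incident
        seg = pt.ArterialSegment(
            id="v", length=40.0, r_prox_dia=0.8, r_dist_dia=0.8,
            p_dia_ref=80 * MMHG,
        )
        c_d = pt.wave_speed(0.8, seg.wall_law, blood)
        Z_c = blood.rho * c_d / float(seg.area_d(1.0))
        T, n = 0.8, 2048
        t = np.arange(n) * T / n
        q = 3.0 * np.exp(-0.5 * ((t - 0.04) / 0.007) ** 2)
        net = pt.VascularNetwork(
            segments=[seg],
            topology={"in": [("v", "prox")], "out": [("v", "dist")]},
            boundaries=[
                pt.BoundaryCondition(
                    "in", "inflow_Q",
                    {"waveform": pt.PeriodicWaveform(t, q, T)},
                ),
                # enormous C: the outlet acts as the pure resistor R1 = Z_c
                # at every frequency the pulse contains
                pt.BoundaryCondition(
                    "out", "wk3",
                    {"R1": Z_c, "C": 5.0, "R2": 1800.0, "P_out": 80 * MMHG},
                ),
            ],
            blood=blood,
        )
        res = pt.run_simulation(
            net, pt.SolverConfig(output_sites=[("v", 0.5)], max_cycles=1)
        )
        p = res.waveform("v", 0.5, "P").values
        tt = res.waveform("v", 0.5, "P").t
        # incident pulse passes x=20 cm at ~0.04 + 20/c; reflection would
        # return at ~0.04 + 60/c
        t_inc = 0.04 + 20.0 / c_d
        t_ref = 0.04 + 60.0 / c_d
        win = 0.04
        inc = np.max(np.abs(p[(tt > t_inc - win) & (tt < t_inc + win)] - p[0]))
        ref = np.max(np.abs(p[(tt > t_ref) & (tt < t_ref + 2 * win)] - p[0]))
        assert ref <= 0.02 * inc


class TestCoronaryOutlet:
    PARAMS = {
        "R_a": 4000.0, "C_a": 4e-6, "R_m": 7000.0, "C_m": 2e-5,
        "R_v_out": 2000.0, "P_out": 5 * MMHG, "gamma_im": 1.0, "alpha": 1.0,
    }

    def _march(self, gamma, P_drive=95 * MMHG, cycles=8):
        """Drive the coronary chain through R_a from a constant pressure."""
        lv = pt.synthetic_lv_pressure(HR=60, peak=120.0)
        params = dict(self.PARAMS, gamma_im=gamma, lv_pressure=lv)
        dt = 1e-3
        n = 1000
        state = np.array([P_drive * 0.9, P_drive * 0.9 - gamma * lv(0.0)])
        Q = 0.0
        q_hist = np.zeros(n)
        for cyc in range(cycles):
            for k in range(n):
                t0, t1 = k * dt, (k + 1) * dt
                # implicit coupling: Q_new from P_drive = P_a_new + R_a Q_new
                from pulsetrim.solver import _wkcor_b0, _wkcor_matrices

                _, S, T = _wkcor_matrices(params, dt)
                b0 = _wkcor_b0(params, lv(t0))
                b0[0] += Q / params["C_a"]
                b1 = _wkcor_b0(params, lv(t1))
                Sinv = np.linalg.inv(S)
                X0 = Sinv @ (T @ state + 0.5 * dt * (b0 + b1))
                XQ = Sinv @ np.array([0.5 * dt / params["C_a"], 0.0])
                Q_new = (P_drive - X0[0]) / (params["R_a"] + XQ[0])
                state = X0 + Q_new * XQ
                Q = Q_new
                q_hist[k] = Q
        return q_hist, lv

    def test_zero_lv_pressure_reduces_to_rcr_chain(self):
        lv0 = pt.PeriodicWaveform(
            np.arange(100) * 0.01, np.zeros(100), 1.0
        )
        params = dict(self.PARAMS, lv_pressure=lv0)
        Q0 = 0.01
        state = np.array([5 * MMHG, 5 * MMHG])
        dt = 1e-3
        for _ in range(60000):
            P, state = wkcor_outlet_step(Q0, Q0, state, params, 0.0, 0.0, dt)
        expect = params["P_out"] + (
            params["R_a"] + params["R_m"] + params["R_v_out"]
        ) * Q0
        assert P == pytest.approx(expect, rel=1e-5)

    def test_systolic_flow_suppressed_at_constant_driving_pressure(self):
        q, lv = self._march(gamma=1.0)
        n = len(q)
        systole = q[: int(0.35 * n)]
        diastole = q[int(0.45 * n):]
        assert systole.mean() < diastole.mean()

    def test_stronger_intramyocardial_pressure_lowers_systolic_share(self):
        shares = []
        for gamma in (0.5, 1.0, 2.0):
            q, _ = self._march(gamma=gamma)
            n = len(q)
            sys_vol = q[: int(0.35 * n)].sum()
            shares.append(sys_vol / q.sum())
        assert shares[0] > shares[1] > shares[2]


class TestSolverRobustness:
    def test_global_mass_balance_within_half_percent_of_stroke_volume(
        self, tree_baseline
    ):
        net, res = tree_baseline
        SV = net.inflow_boundary.params["waveform"].integral()
        vol_in = res.waveform("s", 0.0, "Q").integral()
        vol_out = sum(
            res.waveform(t, 1.0, "Q").integral()
            for t in ("s00", "s01", "s10", "s11")
        )
        assert abs(vol_in - vol_out) <= 0.005 * SV

    def test_periodicity_residual_reported_and_below_tolerance(
        self, tree_baseline
    ):
        _, res = tree_baseline
        assert res.converged
        assert res.periodicity_residual <= 1e-3

    def test_nonconvergence_is_flagged_not_raised(self, single_vessel):
        cfg = pt.SolverConfig(
            output_sites=[("v0", 0.5)], max_cycles=2, periodicity_tol=1e-12
        )
        res = pt.run_simulation(single_vessel, cfg)
        assert not res.converged

    def test_stenotic_span_removed_from_grid(self, toy_coronary):
        from pulsetrim.solver import _Grid

        grid = _Grid(toy_coronary, pt.SolverConfig(output_sites=[]))
        pieces = grid.piece_map["cor_sten"][0]
        assert len(pieces) == 2  # split around the stenosis
        assert any("stenosis" in name for name, _, _ in grid.junctions)
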