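"""Method 1: Picard steady solve, lumped parameters and truncation."""

import numpy as np
import pytest

import pulsetrim as pt
from pulsetrim.method1 import input_resistance
from pulsetrim.testkit import oracle_nodal_analysis
from pulsetrim.units import MMHG
from conftest import random_tree


def nodal_oracle_check(net, ss, rtol=1e-8):
    """Rebuild the frozen-area linear network and solve it independently."""
    edges = []
    keys = []
    for seg in net.segments:
        R = pt.segment_viscous_resistance(
            seg, net.blood, ss.area_profile(seg.id), n_quad=51
        )
        for st in net.stenoses_on(seg.id):
            R += st.K_visc + st.K_exp * abs(ss.segment_flow[seg.id])
        edges.append((net.node_of(seg.id, "prox"),
                      net.node_of(seg.id, "dist"), R))
        keys.append(seg.id)
    for b in net.boundaries:
        if not b.is_inflow:
            edges.append((b.node, None, b.total_resistance,
                          b.params["P_out"]))
            keys.append(None)
    Q_in = net.inflow_boundary.params["waveform"].mean()
    pressures, flows = oracle_nodal_analysis(
        edges, injections={net.inflow_node: Q_in}
    )
    for node, P in ss.node_pressure.items():
        assert P == pytest.approx(pressures[node], rel=rtol)
    for k, sid in enumerate(keys):
        if sid is not None:
            assert ss.segment_flow[sid] == pytest.approx(
                flows[k], rel=rtol, abs=rtol * Q_in
            )


class TestSteadySolve:
    def test_single_vessel_series_resistance_exact(self, single_vessel):
        net = single_vessel
        ss = pt.solve_steady(net)
        out = next(b for b in net.boundaries if not b.is_inflow)
        Q = net.inflow_boundary.params["waveform"].mean()
        R_v = pt.segment_viscous_resistance(
            net.segments[0], net.blood, ss.area_profile("v0")
        )
        expect = out.params["P_out"] + (
            R_v + out.params["R1"] + out.params["R2"]
        ) * Q
        assert ss.node_pressure["in"] == pytest.approx(expect, rel=1e-10)

    def test_symmetric_tree_sibling_flows_equal(self, tree3):
        ss = pt.solve_steady(tree3)
        assert ss.segment_flow["s0"] == pytest.approx(
            ss.segment_flow["s1"], rel=1e-10
        )
        assert ss.segment_flow["s00"] == pytest.approx(
            ss.segment_flow["s11"], rel=1e-10
        )

    def test_ring_network_matches_nodal_oracle(self, ring):
        ss = pt.solve_steady(ring)
        nodal_oracle_check(ring, ss)

    def test_random_trees_match_nodal_oracle(self):
        rng = np.random.default_rng(20240915)
        for _ in range(20):
            net = random_tree(rng)
            ss = pt.solve_steady(net)
            nodal_oracle_check(net, ss)

    def test_junction_mass_conservation(self, tree3):
        ss = pt.solve_steady(tree3)
        for node, ports in tree3.topology.items():
            if tree3.boundary_at(node) is not None:
                continue
            total = 0.0
            for sid, end in ports:
                sgn = 1.0 if end == "dist" else -1.0
                total += sgn * ss.segment_flow[sid]
            assert abs(total) < 1e-8 * abs(
                tree3.inflow_boundary.params["waveform"].mean()
            )

    def test_stenosis_chord_linearization_reproduces_nonlinear_drop(
        self, tree3
    ):
        net = pt.insert_coarctation(tree3, "s", 1.0, 0.5)
        ss = pt.solve_steady(net)
        st = net.stenoses[0]
        Q = ss.segment_flow["s"]
        # converged Picard drop across the stenosis equals the nonlinear law
        R_v = pt.segment_viscous_resistance(
            net.segment("s"), net.blood, ss.area_profile("s"), n_quad=51
        )
        drop = ss.node_pressure["in"] - ss.node_pressure["ns"]
        assert drop == pytest.approx(
            R_v * Q + st.pressure_loss(Q), rel=1e-6
        )


class TestLumpedParameters:
    def test_terminal_site_resistance_is_series_sum(self, single_vessel):
        ss = pt.solve_steady(single_vessel)
        out = next(b for b in single_vessel.boundaries if not b.is_inflow)
        R = pt.lumped_resistance(ss, ("v0", 0.0), out.params["P_out"])
        R_v = pt.segment_viscous_resistance(
            single_vessel.segments[0], single_vessel.blood,
            ss.area_profile("v0"),
        )
        assert R == pytest.approx(
            R_v + out.params["R1"] + out.params["R2"], rel=1e-9
        )

    def test_bifurcation_inlet_sees_parallel_daughters(self, tree3):
        # 2-generation cut: parent viscous + half of one daughter path
        ss = pt.solve_steady(tree3)
        out = next(
            b for b in tree3.boundaries
            if not b.is_inflow and b.node == "ns00"
        )
        P_out = out.params["P_out"]
        R_root = pt.lumped_resistance(ss, ("s", 0.0), P_out)
        edges = []
        for seg in tree3.segments:
            edges.append(pt.segment_viscous_resistance(
                seg, tree3.blood, ss.area_profile(seg.id)
            ))
        R_term = {
            b.node: b.total_resistance
            for b in tree3.boundaries if not b.is_inflow
        }
        ids = [s.id for s in tree3.segments]
        Rv = dict(zip(ids, edges))
        path = lambda leaf, term: Rv[leaf] + R_term[term]
        R_gen2 = {
            "s0": Rv["s0"] + 1 / (1 / path("s00", "ns00") + 1 / path("s01", "ns01")),
            "s1": Rv["s1"] + 1 / (1 / path("s10", "ns10") + 1 / path("s11", "ns11")),
        }
        expect = Rv["s"] + 1 / (1 / R_gen2["s0"] + 1 / R_gen2["s1"])
        assert R_root == pytest.approx(expect, rel=1e-8)

    def test_degenerate_pressure_gives_zero(self, single_vessel):
        ss = pt.solve_steady(single_vessel)
        P_here = ss.pressure_at("v0", 0.5)
        assert pt.lumped_resistance(ss, ("v0", 0.5), P_here) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_no_flow_branch_rejected(self, single_vessel):
        ss = pt.solve_steady(single_vessel)
        ss.segment_flow["v0"] = 0.0
        with pytest.raises(pt.ValidationError):
            pt.lumped_resistance(ss, ("v0", 0.5), 0.0)


class TestLumpedCompliance:
    def test_terminal_formula_limiting_case(self):
        # C_v = 0, R_v = 0: C_t = C*R2/(R1+R2)
        from pulsetrim.method1 import terminal_compliance_formula

        C_t = terminal_compliance_formula(0.0, 1.0, 0.1, 1.0, 0.0)
        assert C_t == pytest.approx(1.0 * 1.0 / 1.1, rel=1e-14)

    def test_terminal_formula_hand_value(self):
        # C_v=0.1, C=1.0, R1=0.1, R2=1.0, R_v=0.05 -> 1.115/1.15
        from pulsetrim.method1 import terminal_compliance_formula

        C_t = terminal_compliance_formula(0.1, 1.0, 0.1, 1.0, 0.05)
        assert C_t == pytest.approx(1.115 / 1.15, abs=1e-12)

    def test_coronary_terminal_adds_chain_compliances(self, toy_coronary):
        ss = pt.solve_steady(toy_coronary)
        seg = toy_coronary.segment("cor_free")
        bc = toy_coronary.boundary_at("t_free")
        C_t = pt.lumped_compliance(toy_coronary, ss, ("cor_free", 0.0))
        C_v = pt.segment_volume_compliance(
            seg, toy_coronary.blood, ss.area_profile("cor_free"), n_quad=51
        )
        assert C_t == pytest.approx(
            C_v + bc.params["C_a"] + bc.params["C_m"], rel=1e-10
        )

    def test_distal_sum_matches_independent_bookkeeping(self, tree3):
        ss = pt.solve_steady(tree3)
        C = pt.lumped_compliance(tree3, ss, ("s", 1.0))
        from pulsetrim.method1 import _terminal_compliance

        total = 0.0
        for sid in ("s0", "s1"):
            seg = tree3.segment(sid)
            total += pt.segment_volume_compliance(
                seg, tree3.blood, ss.area_profile(sid), n_quad=51
            )
        for sid in ("s00", "s01", "s10", "s11"):
            seg = tree3.segment(sid)
            bc = tree3.boundary_at(f"n{sid}")
            total += _terminal_compliance(tree3, ss, seg, bc)
        assert C == pytest.approx(total, rel=1e-10)


class TestCharacteristicImpedance:
    def test_direct_evaluation(self):
        # Z_c = rho c / A = 1.06 * 460.6 / 0.5
        assert 1.06 * 460.6 / 0.5 == pytest.approx(976.5, abs=0.1)

    def test_scales_inversely_with_area(self, tree3):
        ss = pt.solve_steady(tree3)
        Z_root = pt.characteristic_impedance(tree3.segment("s"), ss, 0.5)
        rho = tree3.blood.rho
        assert Z_root == pytest.approx(
            rho * ss.wave_speed_at("s", 0.5) / ss.area_at("s", 0.5), rel=1e-12
        )

    def test_diastolic_vs_mean_state_within_ten_percent(self, tree3):
        ss = pt.solve_steady(tree3)
        for seg in tree3.segments:
            Z_mean = pt.characteristic_impedance(seg, ss, 1.0)
            c_d = pt.wave_speed(seg.r_dist_dia, seg.wall_law, tree3.blood)
            Z_dia = tree3.blood.rho * c_d / float(seg.area_d(1.0))
            assert abs(Z_mean - Z_dia) / Z_dia < 0.10


class TestTruncation:
    def test_retain_all_is_identity(self, tree3):
        ss = pt.solve_steady(tree3)
        red = pt.truncate_network(tree3, ss, [s.id for s in tree3.segments])
        assert [s.id for s in red.segments] == [s.id for s in tree3.segments]
        assert len(red.boundaries) == len(tree3.boundaries)

    def test_root_cut_preserves_steady_inlet_pressure(self, tree3):
        ss = pt.solve_steady(tree3)
        red = pt.truncate_network(tree3, ss, ["s"])
        ss_red = pt.solve_steady(red)
        assert ss_red.node_pressure["in"] == pytest.approx(
            ss.node_pressure["in"], rel=1e-6
        )

    def test_generation_cut_preserves_input_resistance(self, tree3):
        ss = pt.solve_steady(tree3)
        red = pt.truncate_network(tree3, ss, ["s", "s0", "s1"])
        assert input_resistance(red) == pytest.approx(
            input_resistance(tree3, ss), rel=1e-6
        )

    def test_compliance_bookkeeping_on_cut(self, tree3):
        ss = pt.solve_steady(tree3)
        red = pt.truncate_network(tree3, ss, ["s"])
        wk = next(b for b in red.boundaries if not b.is_inflow)
        assert wk.params["C"] == pytest.approx(
            pt.lumped_compliance(tree3, ss, ("s", 1.0)), rel=1e-12
        )
        # physical sanity: totals agree to the linearization-state level
        assert red.total_compliance() == pytest.approx(
            tree3.total_compliance(), rel=0.15
        )

    def test_mixed_junction_rejected(self, tree3):
        ss = pt.solve_steady(tree3)
        with pytest.raises(pt.ValidationError, match="mixed"):
            pt.truncate_network(tree3, ss, ["s", "s0", "s1", "s00"])

    def test_lumping_below_characteristic_impedance_rejected(self, tree3):
        ss = pt.solve_steady(tree3)
        # make the distal bed resistance tiny so R_lumped < Z_c at the cut
        cheap = tree3.copy()
        for b in cheap.boundaries:
            if not b.is_inflow:
                b.params["R2"] = 1.0
                b.params["R1"] = 0.5
                b.params["P_out"] = 79.9 * MMHG
        ss2 = pt.solve_steady(cheap)
        with pytest.raises(pt.ValidationError, match="Z_c"):
            pt.truncate_network(cheap, ss2, ["s"])
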