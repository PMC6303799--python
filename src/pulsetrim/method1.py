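"""Method 1: algebraic network reduction.

A steady, linearized version of the 1D equations is solved by Picard
iteration: with vessel areas frozen, the network is a linear resistive
circuit (nodal analysis); node pressures then update the areas through the
tube law, and the sweep repeats until the pressures are stationary.  From
the steady solution, any distal subtree can be replaced by a Windkessel
outlet whose resistance is (P - P_out)/Q at the cut (Ohm's law), whose
proximal resistance is the local characteristic impedance Z_c = rho*c/A,
and whose compliance is the parallel sum of the distal volume compliances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    BoundaryCondition,
    ValidationError,
    VascularNetwork,
    segment_viscous_resistance,
    segment_volume_compliance,
)

__all__ = [
    "SteadySolution",
    "LumpedOutlet",
    "solve_steady",
    "lumped_resistance",
    "lumped_compliance",
    "characteristic_impedance",
    "terminal_compliance_formula",
    "truncate_network",
    "input_resistance",
]

_N_QUAD = 51  # per-segment quadrature nodes for the steady profiles


@dataclass
class SteadySolution:
    """Network-wide mean pressures, flows and areas from the steady solve."""

    node_pressure: dict           # node -> P (dyn/cm^2)
    segment_flow: dict            # seg_id -> Q (cm^3/s), positive prox->dist
    profiles: dict                # seg_id -> dict(s, P, A, c, R_cum)
    iterations: int
    residual: float
    net: VascularNetwork = field(repr=False, default=None)

    def flow_at(self, seg_id, pos=0.5) -> float:
        return self.segment_flow[seg_id]

    def pressure_at(self, seg_id, pos) -> float:
        prof = self.profiles[seg_id]
        return float(np.interp(pos, prof["s"], prof["P"]))

    def area_at(self, seg_id, pos) -> float:
        prof = self.profiles[seg_id]
        return float(np.interp(pos, prof["s"], prof["A"]))

    def wave_speed_at(self, seg_id, pos) -> float:
        prof = self.profiles[seg_id]
        return float(np.interp(pos, prof["s"], prof["c"]))

    def area_profile(self, seg_id):
        prof = self.profiles[seg_id]
        return lambda s: np.interp(s, prof["s"], prof["A"])


@dataclass
class LumpedOutlet:
    """Windkessel parameter set replacing a truncated subtree."""

    site: tuple                   # (segment_id, position)
    kind: str                     # "wk3" | "wk_cor"
    params: dict


def _segment_series_resistance(seg, net, area_profile, Q_prev):
    """R_v plus chord-linearized stenosis resistances of one segment."""
    blood = net.blood
    R = segment_viscous_resistance(seg, blood, area_profile, n_quad=_N_QUAD)
    for st in net.stenoses_on(seg.id):
        R += st.K_visc + st.K_exp * abs(Q_prev)
    return R


def solve_steady(
    net: VascularNetwork,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> SteadySolution:
    """Picard-linearized steady solve of the network.

    Static-pressure continuity is used at junctions (the mean-flow dynamic
    head is negligible at the linearization state), which makes each sweep
    a single linear nodal-analysis solve.
    """
    nodes = list(net.topology.keys())
    n_idx = {n: k for k, n in enumerate(nodes)}
    nn = len(nodes)
    blood = net.blood

    inflow = net.inflow_boundary
    if inflow.variant == "inflow_Q":
        Q_in = inflow.params["waveform"].mean()
        P_in_fixed = None
    else:
        Q_in = None
        P_in_fixed = inflow.params["waveform"].mean()

    # initial areas: diastolic
    areas = {s.id: (lambda sv, seg=s: seg.area_d(sv)) for s in net.segments}
    seg_Q = {s.id: 0.0 for s in net.segments}
    P_nodes = np.array(
        [np.mean([net.segment(sid).p_dia_ref
                  for sid, _ in net.topology[n]]) for n in nodes]
    )

    seg_ends = {
        s.id: (net.node_of(s.id, "prox"), net.node_of(s.id, "dist"))
        for s in net.segments
    }

    it = 0
    residual = np.inf
    for it in range(1, max_iter + 1):
        G = np.zeros((nn, nn))
        rhs = np.zeros(nn)
        seg_R = {}
        for seg in net.segments:
            R = _segment_series_resistance(
                seg, net, areas[seg.id], seg_Q[seg.id]
            )
            seg_R[seg.id] = R
            g = 1.0 / R
            a, b = (n_idx[x] for x in seg_ends[seg.id])
            G[a, a] += g
            G[b, b] += g
            G[a, b] -= g
            G[b, a] -= g
        for bc in net.boundaries:
            k = n_idx[bc.node]
            if bc.is_inflow:
                continue
            g = 1.0 / bc.total_resistance
            G[k, k] += g
            rhs[k] += g * bc.params["P_out"]
        k_in = n_idx[inflow.node]
        if Q_in is not None:
            rhs[k_in] += Q_in
        else:
            G[k_in, :] = 0.0
            G[k_in, k_in] = 1.0
            rhs[k_in] = P_in_fixed
        try:
            P_new = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"steady solve singular: {exc}") from None

        residual = float(
            np.max(np.abs(P_new - P_nodes) / np.maximum(np.abs(P_new), 1.0))
        )
        P_nodes = P_new

        # update flows and area profiles from the new pressures
        new_areas = {}
        for seg in net.segments:
            a, b = seg_ends[seg.id]
            Pa, Pb = P_nodes[n_idx[a]], P_nodes[n_idx[b]]
            Qs = (Pa - Pb) / seg_R[seg.id]
            seg_Q[seg.id] = Qs
            sgrid = np.linspace(0.0, 1.0, _N_QUAD)
            # pressure varies along the cumulative viscous resistance
            A_cur = np.asarray(areas[seg.id](sgrid), float)
            integrand = blood.friction_factor * math.pi * blood.mu / (A_cur**2)
            x = sgrid * seg.length
            R_cum = np.concatenate(
                [[0.0], np.cumsum(
                    0.5 * (integrand[1:] + integrand[:-1]) * np.diff(x)
                )]
            )
            # distribute the total drop (incl. stenoses) proportionally
            if R_cum[-1] > 0:
                Pprof = Pa - (Pa - Pb) * R_cum / R_cum[-1]
            else:
                Pprof = np.full_like(sgrid, Pa)
            A_d = seg.area_d(sgrid)
            beta = seg.beta(sgrid)
            root = np.sqrt(A_d) + (Pprof - seg.p_dia_ref) * A_d / beta
            if np.any(root <= 0):
                raise ValidationError(
                    f"steady solve: collapse in segment {seg.id}"
                )
            A_new = root * root
            new_areas[seg.id] = (
                lambda sv, sg=sgrid, av=A_new: np.interp(sv, sg, av)
            )
        areas = new_areas
        if residual <= tol:
            break
    else:
        raise ValidationError(
            f"steady solve did not converge in {max_iter} Picard sweeps"
        )

    profiles = {}
    for seg in net.segments:
        a, b = seg_ends[seg.id]
        Pa, Pb = P_nodes[n_idx[a]], P_nodes[n_idx[b]]
        sgrid = np.linspace(0.0, 1.0, _N_QUAD)
        A_bar = np.asarray(areas[seg.id](sgrid), float)
        A_d = seg.area_d(sgrid)
        beta = seg.beta(sgrid)
        Pprof = seg.p_dia_ref + beta / A_d * (np.sqrt(A_bar) - np.sqrt(A_d))
        c_bar = np.sqrt(beta * np.sqrt(A_bar) / (2.0 * blood.rho * A_d))
        x = sgrid * seg.length
        integrand = blood.friction_factor * math.pi * blood.mu / (A_bar**2)
        R_cum = np.concatenate(
            [[0.0], np.cumsum(
                0.5 * (integrand[1:] + integrand[:-1]) * np.diff(x)
            )]
        )
        profiles[seg.id] = {
            "s": sgrid, "P": Pprof, "A": A_bar, "c": c_bar, "R_cum": R_cum,
        }
    return SteadySolution(
        node_pressure={n: float(P_nodes[n_idx[n]]) for n in nodes},
        segment_flow=dict(seg_Q),
        profiles=profiles,
        iterations=it,
        residual=residual,
        net=net,
    )


def lumped_resistance(ss: SteadySolution, site, P_out: float) -> float:
    """Ohm's-law lumped resistance (P(site) - P_out)/Q(site)."""
    seg_id, pos = site
    Q = ss.flow_at(seg_id, pos)
    if abs(Q) < 1e-12:
        raise ValidationError(
            f"cannot lump at {site}: no mean flow through the site"
        )
    return (ss.pressure_at(seg_id, pos) - P_out) / Q


def characteristic_impedance(segment, ss: SteadySolution, pos=1.0) -> float:
    """Z_c = rho * c / A at the cut face, using the steady mean state."""
    rho = ss.net.blood.rho
    return rho * ss.wave_speed_at(segment.id, pos) / ss.area_at(segment.id, pos)


def _distal_segments(net: VascularNetwork, seg_id: str):
    """Segments strictly distal of segment seg_id (beyond its dist node)."""
    g = net.as_graph()
    prox = net.node_of(seg_id, "prox")
    dist = net.node_of(seg_id, "dist")
    g.remove_edge(prox, dist, key=seg_id)
    import networkx as nx

    comp = nx.node_connected_component(g, dist) if dist in g else {dist}
    if net.inflow_node in comp and net.inflow_node != dist:
        raise ValidationError(
            f"distal side of {seg_id} reaches the inflow; cannot lump"
        )
    return [
        s.id for s in net.segments
        if s.id != seg_id
        and net.node_of(s.id, "prox") in comp
        and net.node_of(s.id, "dist") in comp
    ]


def _terminal_bc_of(net: VascularNetwork, seg_id: str):
    for end in ("dist", "prox"):
        bc = net.boundary_at(net.node_of(seg_id, end))
        if bc is not None and not bc.is_inflow:
            return bc
    return None


def terminal_compliance_formula(C_v, C, R1, R2, R_v) -> float:
    """Lumped compliance of a vessel (C_v, R_v) feeding a WK3 (R1, C, R2)."""
    return (C_v * R2 + C_v * R1 + C * R2 + C_v * R_v) / (R2 + R1 + R_v)


def _terminal_compliance(net, ss, seg, bc, s_from=0.0) -> float:
    """Lumped compliance C_t of a terminal vessel with its outlet model."""
    blood = net.blood
    prof = ss.area_profile(seg.id)
    frac = 1.0 - s_from
    sub = lambda sv: prof(s_from + np.asarray(sv) * frac)
    # partial-vessel C_v and R_v from s_from to the terminal end
    C_v = segment_volume_compliance(seg, blood, sub, _N_QUAD) * frac
    if bc.variant == "wk_cor":
        return C_v + bc.params["C_a"] + bc.params["C_m"]
    R_v = segment_viscous_resistance(seg, blood, sub, _N_QUAD) * frac
    return terminal_compliance_formula(
        C_v, bc.params["C"], bc.params["R1"], bc.params["R2"], R_v
    )


def lumped_compliance(net: VascularNetwork, ss: SteadySolution, site) -> float:
    """Total compliance of everything distal of the site (parallel addition).

    Terminal vessels contribute C_t (their volume compliance combined with
    the outlet Windkessel), non-terminal vessels contribute their volume
    compliance C_v; arterial compliances share the external reference
    pressure, so contributions add in parallel (plain sum).
    """
    seg_id, pos = site
    seg = net.segment(seg_id)
    distal = _distal_segments(net, seg_id)
    bc_host = _terminal_bc_of(net, seg_id)
    total = 0.0
    if bc_host is not None and not distal:
        return _terminal_compliance(net, ss, seg, bc_host, s_from=pos)
    # host's own remaining span is non-terminal
    frac = 1.0 - pos
    if frac > 0:
        prof = ss.area_profile(seg_id)
        sub = lambda sv: prof(pos + np.asarray(sv) * frac)
        total += segment_volume_compliance(seg, net.blood, sub, _N_QUAD) * frac
    for sid in distal:
        s = net.segment(sid)
        bc = _terminal_bc_of(net, sid)
        if bc is None:
            total += segment_volume_compliance(
                s, net.blood, ss.area_profile(sid), _N_QUAD
            )
        else:
            total += _terminal_compliance(net, ss, s, bc)
    return total


def _cut_faces(net: VascularNetwork, retained_ids):
    """Cut faces implied by a retained set; raises on mixed junctions.

    Returns a list of (retained_seg_id, end, node, removed_outlet_bcs).
    """
    retained = set(retained_ids)
    all_ids = {s.id for s in net.segments}
    unknown = retained - all_ids
    if unknown:
        raise ValidationError(f"unknown segment ids {sorted(unknown)}")
    removed = all_ids - retained
    if not removed:
        return []
    # retained part must contain the inflow and be connected
    import networkx as nx

    g = net.as_graph()
    gr = nx.MultiGraph()
    gr.add_nodes_from(g.nodes)
    for sid in retained:
        gr.add_edge(net.node_of(sid, "prox"), net.node_of(sid, "dist"), key=sid)
    gr.remove_nodes_from([n for n in list(gr.nodes) if gr.degree(n) == 0
                          and n != net.inflow_node])
    if not nx.is_connected(gr):
        raise ValidationError("retained segments are not connected")
    inflow_sid = net.topology[net.inflow_node][0][0]
    if inflow_sid not in retained:
        raise ValidationError("retained set must contain the inflow segment")

    faces = []
    for node, ports in net.topology.items():
        ports = [tuple(p) for p in ports]
        kept = [p for p in ports if p[0] in retained]
        cut = [p for p in ports if p[0] in removed]
        if not cut or not kept:
            continue
        if len(kept) != 1:
            raise ValidationError(
                f"mixed junction at {node}: all branches distal of a junction "
                "must be removed together"
            )
        sid, end = kept[0]
        faces.append((sid, end, node))
    # collect removed outlets per face by graph component
    g_rem = nx.MultiGraph()
    for sid in removed:
        g_rem.add_edge(net.node_of(sid, "prox"), net.node_of(sid, "dist"), key=sid)
    out = []
    for sid, end, node in faces:
        comp = nx.node_connected_component(g_rem, node)
        bcs = [
            b for b in net.boundaries
            if (not b.is_inflow) and b.node in comp
        ]
        if not bcs:
            raise ValidationError(f"removed side at {node} has no outlets")
        out.append((sid, end, node, bcs))
    return out


def truncate_network(
    net: VascularNetwork,
    ss: SteadySolution,
    retained_ids,
    coronary_r_split=(0.32, 0.52, 0.16),
    coronary_c_split=(0.11, 0.89),
) -> VascularNetwork:
    """Replace everything distal of the retained set with Windkessel outlets.

    Systemic cut faces get a WK3 with R1 = Z_c, R2 = R_lumped - Z_c and
    C = C_lumped; coronary faces get a coronary Windkessel whose lumped
    totals are divided among the chain elements by the configured ratios.
    """
    faces = _cut_faces(net, retained_ids)
    retained = set(retained_ids)
    if not faces:
        return net.copy()

    new_bcs = []
    for sid, end, node, bcs in faces:
        seg = net.segment(sid)
        pos = 1.0 if end == "dist" else 0.0
        sgn = 1.0 if end == "dist" else -1.0
        Q_cut = sgn * ss.flow_at(sid, pos)
        if Q_cut <= 0:
            raise ValidationError(
                f"cut face at {node} has non-positive mean flow; retain more"
            )
        p_outs = [b.params["P_out"] for b in bcs]
        P_out = float(np.mean(p_outs))
        R_lump = (ss.pressure_at(sid, pos) - P_out) / Q_cut
        C_lump = lumped_compliance(net, ss, (sid, pos))
        kinds = {b.variant for b in bcs}
        if kinds == {"wk_cor"}:
            fa, fm, fv = coronary_r_split
            ca, cm = coronary_c_split
            ref = bcs[0]
            new_bcs.append(BoundaryCondition(
                node=node, variant="wk_cor",
                params={
                    "R_a": fa * R_lump, "R_m": fm * R_lump,
                    "R_v_out": fv * R_lump,
                    "C_a": ca * C_lump, "C_m": cm * C_lump,
                    "P_out": P_out,
                    "gamma_im": ref.params["gamma_im"],
                    "lv_pressure": ref.params["lv_pressure"],
                    "alpha": ref.params["alpha"],
                },
            ))
        else:
            Z_c = characteristic_impedance(seg, ss, pos)
            if R_lump <= Z_c:
                raise ValidationError(
                    f"lumping invalid at {node}: lumped resistance "
                    f"{R_lump:.3g} <= Z_c {Z_c:.3g}; retain more vessels"
                )
            new_bcs.append(BoundaryCondition(
                node=node, variant="wk3",
                params={"R1": Z_c, "C": C_lump, "R2": R_lump - Z_c,
                        "P_out": P_out},
            ))

    keep_nodes = set()
    topo = {}
    for node, ports in net.topology.items():
        kept = [tuple(p) for p in ports if p[0] in retained]
        if kept:
            topo[node] = kept
            keep_nodes.add(node)
    boundaries = [
        b for b in net.boundaries if b.node in keep_nodes
        and all(tuple(p)[0] in retained for p in net.topology[b.node])
    ]
    boundaries += new_bcs
    return VascularNetwork(
        segments=[s for s in net.segments if s.id in retained],
        topology=topo,
        stenoses=[st for st in net.stenoses if st.segment_id in retained],
        boundaries=boundaries,
        blood=net.blood,
    )


def input_resistance(net: VascularNetwork, ss: SteadySolution | None = None) -> float:
    """Total input resistance (P_in - P_out)/Q_in from the steady solve."""
    if ss is None:
        ss = solve_steady(net)
    inflow = net.inflow_boundary
    if inflow.variant != "inflow_Q":
        raise ValidationError("input resistance needs a prescribed-flow inlet")
    Q = inflow.params["waveform"].mean()
    P_in = ss.node_pressure[inflow.node]
    p_outs = [b.params["P_out"] for b in net.boundaries if not b.is_inflow]
    return (P_in - float(np.mean(p_outs))) / Q
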