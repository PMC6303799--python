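"""Deterministic synthetic fixtures and closed-form oracles.

Toy networks (single vessel, symmetric binary trees, a ring with outlets
and a small coronary tree with one stenosis) plus synthetic inflow and
left-ventricular pressure waveforms, sized so that every stage of the
pipeline can be exercised without external data.  The oracles are
independent closed-form references used to cross-check the numerical
implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    ArterialSegment,
    BloodProperties,
    BoundaryCondition,
    CORONARY_WALL_LAW,
    PeriodicWaveform,
    StenosisDescriptor,
    SYSTEMIC_WALL_LAW,
    ValidationError,
    VascularNetwork,
    wave_speed,
    young_tsai_coefficients,
)
from .scenarios import distribute_coronary_outlet_params
from .units import MMHG

__all__ = [
    "ToyNetworkSpec",
    "make_fixture",
    "random_tree",
    "synthetic_inflow",
    "synthetic_lv_pressure",
    "oracle_poiseuille_drop",
    "oracle_wk_decay",
    "oracle_wk3_impedance",
    "oracle_linear_wave_speed",
    "oracle_nodal_analysis",
]

# nominal toy haemodynamics: aorta-like root perfused at ~100 mmHg mean
_P_TARGET = 100.0 * MMHG
_P_OUT = 5.0 * MMHG
_P_DIA = 80.0 * MMHG
_TAU_WK = 0.35       # WK3 R2*C time constant, s (fast periodic convergence)
_Q_MEAN = 70.0       # nominal mean inflow, cm^3/s


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Family and geometry of a synthetic network.

    Daughter radii follow the Murray-consistent rule r_child = r * 2^(-1/3);
    lengths halve each generation.
    """

    family: str = "single_vessel"   # single_vessel | binary_tree |
                                    # ring_with_outlets | toy_coronary
    generations: int = 3
    stenosis_area_ratio: float = 0.25
    base_radius: float = 1.0        # cm
    base_length: float = 10.0       # cm
    q_mean: float = _Q_MEAN         # nominal mean inflow, cm^3/s
    p_target: float = _P_TARGET     # target mean root pressure
    inflow: PeriodicWaveform | None = None


def synthetic_inflow(HR: float = 60.0, ET: float = 0.3, SV: float = 70.0,
                     n: int = 512) -> PeriodicWaveform:
    """Half-sine ejection over ET scaled to SV, zero in diastole."""
    T = 60.0 / HR
    if ET >= T:
        raise ValidationError("ET must be shorter than the period")
    t = np.arange(n) * (T / n)
    q = np.where(t < ET, np.sin(np.pi * np.clip(t, 0, ET) / ET), 0.0)
    q *= SV / (np.sum(q) * T / n)
    return PeriodicWaveform(t, q, T)


def synthetic_lv_pressure(HR: float = 60.0, peak: float = 120.0,
                          systole_fraction: float = 0.35,
                          n: int = 512) -> PeriodicWaveform:
    """Smooth squared-sine systolic pressure bump (peak in mmHg), zero
    during diastole."""
    T = 60.0 / HR
    t = np.arange(n) * (T / n)
    ts = systole_fraction * T
    p = np.where(t < ts, np.sin(np.pi * np.clip(t, 0, ts) / ts) ** 2, 0.0)
    return PeriodicWaveform(t, peak * MMHG * p, T)


def _wk3_for(seg: ArterialSegment, blood: BloodProperties, R_out: float,
             tau: float = _TAU_WK) -> dict:
    """WK3 params: R1 = Z_c of the attached vessel, R2 from the target."""
    r_d = seg.r_dist_dia
    c_d = wave_speed(r_d, seg.wall_law, blood)
    Z_c = blood.rho * c_d / (math.pi * r_d * r_d)
    R2 = R_out - Z_c
    if R2 <= 0:
        raise ValidationError("toy outlet resistance below Z_c")
    return {"R1": Z_c, "C": tau / R2, "R2": R2, "P_out": _P_OUT}


def make_fixture(spec: ToyNetworkSpec) -> VascularNetwork:
    """Build a deterministic toy network from its spec."""
    blood = BloodProperties()
    inflow_wave = spec.inflow or synthetic_inflow(SV=spec.q_mean)
    q_mean = inflow_wave.mean()
    R_total = (spec.p_target - _P_OUT) / q_mean

    if spec.family == "single_vessel":
        seg = ArterialSegment(
            id="v0", name="vessel", length=spec.base_length,
            r_prox_dia=spec.base_radius, r_dist_dia=spec.base_radius,
            p_dia_ref=_P_DIA,
        )
        return VascularNetwork(
            segments=[seg],
            topology={"in": [("v0", "prox")], "out": [("v0", "dist")]},
            boundaries=[
                BoundaryCondition("in", "inflow_Q", {"waveform": inflow_wave}),
                BoundaryCondition("out", "wk3", _wk3_for(seg, blood, R_total)),
            ],
            blood=blood,
        )

    if spec.family == "binary_tree":
        G = spec.generations
        segments, topo, bcs = [], {}, []
        scale = 2.0 ** (-1.0 / 3.0)

        def build(label, gen, parent_node):
            r = spec.base_radius * scale**gen
            length = spec.base_length * 0.5**gen
            seg = ArterialSegment(
                id=label, length=length, r_prox_dia=r, r_dist_dia=r,
                p_dia_ref=_P_DIA,
            )
            segments.append(seg)
            topo.setdefault(parent_node, []).append((label, "prox"))
            child_node = f"n{label}"
            topo.setdefault(child_node, []).append((label, "dist"))
            if gen == G - 1:
                n_term = 2 ** (G - 1)
                bcs.append(BoundaryCondition(
                    child_node, "wk3",
                    _wk3_for(seg, blood, n_term * R_total),
                ))
            else:
                build(label + "0", gen + 1, child_node)
                build(label + "1", gen + 1, child_node)

        build("s", 0, "in")
        bcs.insert(0, BoundaryCondition("in", "inflow_Q",
                                        {"waveform": inflow_wave}))
        return VascularNetwork(segments=segments, topology=topo,
                               boundaries=bcs, blood=blood)

    if spec.family == "ring_with_outlets":
        r0, L = spec.base_radius, spec.base_length
        rr = r0 * 2.0 ** (-1.0 / 3.0)
        mk = lambda sid, ln, r: ArterialSegment(
            id=sid, length=ln, r_prox_dia=r, r_dist_dia=r, p_dia_ref=_P_DIA
        )
        segments = [
            mk("feed", L / 2, r0),
            mk("arcA", L / 2, rr), mk("arcB", L / 2, rr),
            mk("arcC", L / 2, rr), mk("arcD", L / 2, rr),
            mk("outE", L / 4, rr), mk("outW", L / 4, rr),
        ]
        topo = {
            "in": [("feed", "prox")],
            "n1": [("feed", "dist"), ("arcA", "prox"), ("arcD", "dist")],
            "n2": [("arcA", "dist"), ("arcB", "prox"), ("outE", "prox")],
            "n3": [("arcB", "dist"), ("arcC", "prox")],
            "n4": [("arcC", "dist"), ("arcD", "prox"), ("outW", "prox")],
            "tE": [("outE", "dist")],
            "tW": [("outW", "dist")],
        }
        bcs = [
            BoundaryCondition("in", "inflow_Q", {"waveform": inflow_wave}),
            BoundaryCondition("tE", "wk3",
                              _wk3_for(segments[5], blood, 2 * R_total)),
            BoundaryCondition("tW", "wk3",
                              _wk3_for(segments[6], blood, 2 * R_total)),
        ]
        return VascularNetwork(segments=segments, topology=topo,
                               boundaries=bcs, blood=blood)

    if spec.family == "toy_coronary":
        lv = synthetic_lv_pressure(HR=60.0 / inflow_wave.period)
        mk = lambda sid, ln, rp, rd, law: ArterialSegment(
            id=sid, length=ln, r_prox_dia=rp, r_dist_dia=rd,
            wall_law=law, p_dia_ref=_P_DIA,
        )
        aorta = mk("aorta", 5.0, spec.base_radius, spec.base_radius,
                   SYSTEMIC_WALL_LAW)
        sysb = mk("sys", 5.0, spec.base_radius, spec.base_radius,
                  SYSTEMIC_WALL_LAW)
        cor_s = mk("cor_sten", 4.0, 0.20, 0.18, CORONARY_WALL_LAW)
        cor_h = mk("cor_free", 4.0, 0.20, 0.18, CORONARY_WALL_LAW)
        segments = [aorta, sysb, cor_s, cor_h]
        topo = {
            "in": [("aorta", "prox")],
            "n1": [("aorta", "dist"), ("sys", "prox"),
                   ("cor_sten", "prox"), ("cor_free", "prox")],
            "t_sys": [("sys", "dist")],
            "t_sten": [("cor_sten", "dist")],
            "t_free": [("cor_free", "dist")],
        }
        blood_ = blood
        A0 = float(cor_s.area_d(0.5))
        As = spec.stenosis_area_ratio * A0
        K_visc, K_exp = young_tsai_coefficients(A0, As, 1.0, blood_)
        sten = StenosisDescriptor(
            segment_id="cor_sten", x_start=1.5, length_s=1.0,
            A0=A0, As=As, K_visc=K_visc, K_exp=K_exp,
        )
        cor = distribute_coronary_outlet_params(
            CO=q_mean, mean_Pp=spec.p_target, P_out=_P_OUT,
            outlet_radii={"t_sten": 0.18, "t_free": 0.18},
        )
        fa, fm, fv = 0.32, 0.52, 0.16
        ca, cm = 0.11, 0.89

        def wkcor(node):
            R, C = cor[node]
            return BoundaryCondition(node, "wk_cor", {
                "R_a": fa * R, "R_m": fm * R, "R_v_out": fv * R,
                "C_a": ca * C, "C_m": cm * C, "P_out": _P_OUT,
                "gamma_im": 1.0, "lv_pressure": lv, "alpha": 1.0,
            })

        # systemic branch takes the remaining ~95.5% of the flow
        R_sys = (spec.p_target - _P_OUT) / (q_mean * (1 - 0.045 * 2))
        bcs = [
            BoundaryCondition("in", "inflow_Q", {"waveform": inflow_wave}),
            BoundaryCondition("t_sys", "wk3", _wk3_for(sysb, blood_, R_sys)),
            wkcor("t_sten"),
            wkcor("t_free"),
        ]
        return VascularNetwork(segments=segments, topology=topo,
                               stenoses=[sten], boundaries=bcs, blood=blood_)

    raise ValidationError(f"unknown fixture family {spec.family!r}")


def random_tree(rng, max_generations: int = 3) -> VascularNetwork:
    """Random asymmetric arterial tree with WK3 outlets.

    Deterministic given the generator state; used for property checks of
    the steady solve against the independent nodal-analysis oracle.
    """
    blood = BloodProperties()
    p_target, p_out = _P_TARGET, _P_OUT
    q_mean = float(rng.uniform(40.0, 90.0))
    inflow = synthetic_inflow(SV=q_mean)
    segments, topo, leaves = [], {}, []

    def add(label, parent_node, r, length, gen):
        seg = ArterialSegment(
            id=label, length=length, r_prox_dia=r,
            r_dist_dia=r * float(rng.uniform(0.85, 1.0)),
            p_dia_ref=_P_DIA,
        )
        segments.append(seg)
        topo.setdefault(parent_node, []).append((label, "prox"))
        node = f"n{label}"
        topo.setdefault(node, []).append((label, "dist"))
        if gen < max_generations and rng.random() < 0.7:
            for k in range(2):
                add(
                    f"{label}{k}", node,
                    r * 2 ** (-1 / 3) * float(rng.uniform(0.9, 1.1)),
                    length * float(rng.uniform(0.4, 0.7)), gen + 1,
                )
        else:
            leaves.append((node, seg))

    add("s", "in", float(rng.uniform(0.7, 1.0)), float(rng.uniform(6, 12)), 0)
    R_total = (p_target - p_out) / q_mean
    bcs = [BoundaryCondition("in", "inflow_Q", {"waveform": inflow})]
    for node, seg in leaves:
        c_d = wave_speed(seg.r_dist_dia, seg.wall_law, blood)
        Z_c = blood.rho * c_d / float(seg.area_d(1.0))
        R_out = len(leaves) * R_total
        R2 = max(R_out - Z_c, Z_c)
        bcs.append(BoundaryCondition(
            node, "wk3",
            {"R1": Z_c, "C": _TAU_WK / R2, "R2": R2, "P_out": p_out},
        ))
    return VascularNetwork(
        segments=segments, topology=topo, boundaries=bcs, blood=blood
    )


# ---------------------------------------------------------------------------
# closed-form oracles

def oracle_poiseuille_drop(Q, length, area, blood: BloodProperties):
    """Steady viscous drop dP = 2(zeta+2) pi mu l Q / A^2 in a uniform tube."""
    return blood.friction_factor * math.pi * blood.mu * length * Q / area**2


def oracle_wk_decay(t, P0, P_out, R2, C):
    """Zero-inflow WK pressure decay P(t) = P_out + (P0-P_out) e^(-t/R2C)."""
    return P_out + (P0 - P_out) * np.exp(-np.asarray(t) / (R2 * C))


def oracle_wk3_impedance(omega, R1, C, R2):
    """Complex WK3 input impedance Z(w) = R1 + R2/(1 + j w R2 C)."""
    omega = np.asarray(omega, dtype=float)
    return R1 + R2 / (1.0 + 1j * omega * R2 * C)


def oracle_linear_wave_speed(r_d, law, blood):
    """Alias of the constitutive diastolic wave speed (hand formula)."""
    return math.sqrt(
        2.0 / (3.0 * blood.rho) * (law.k1 * math.exp(law.k2 * r_d) + law.k3)
    )


def oracle_nodal_analysis(edges, injections, dirichlet=None):
    """Dense linear resistive-network solve, independent of solve_steady.

    edges: list of (node_a, node_b, R); grounded edges use node_b=None with
    the pair (R, P_ground).  injections: {node: Q_in}.  dirichlet:
    {node: P_fixed}.  Returns ({node: P}, {edge_index: Q_a_to_b}).
    """
    nodes = []
    for a, b, *_ in edges:
        for n in (a, b):
            if n is not None and n not in nodes:
                nodes.append(n)
    idx = {n: k for k, n in enumerate(nodes)}
    N = len(nodes)
    G = np.zeros((N, N))
    rhs = np.zeros(N)
    for a, b, R, *rest in edges:
        g = 1.0 / R
        ia = idx[a]
        if b is None:
            P_gnd = rest[0]
            G[ia, ia] += g
            rhs[ia] += g * P_gnd
        else:
            ib = idx[b]
            G[ia, ia] += g
            G[ib, ib] += g
            G[ia, ib] -= g
            G[ib, ia] -= g
    for n, q in (injections or {}).items():
        rhs[idx[n]] += q
    for n, p in (dirichlet or {}).items():
        k = idx[n]
        G[k, :] = 0.0
        G[k, k] = 1.0
        rhs[k] = p
    P = np.linalg.solve(G, rhs)
    pressures = {n: float(P[idx[n]]) for n in nodes}
    flows = {}
    for k, (a, b, R, *rest) in enumerate(edges):
        if b is None:
            flows[k] = (pressures[a] - rest[0]) / R
        else:
            flows[k] = (pressures[a] - pressures[b]) / R
    return pressures, flows
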