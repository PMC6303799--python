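"""Physiological and pathological re-parametrizations of a network.

All operations are pure: they return a modified copy and leave the input
network untouched.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq

from .model import (
    PeriodicWaveform,
    StenosisDescriptor,
    ValidationError,
    VascularNetwork,
    young_tsai_coefficients,
)

__all__ = [
    "apply_ageing",
    "insert_coarctation",
    "rescale_inflow",
    "set_hyperaemia",
    "distribute_coronary_outlet_params",
]


def apply_ageing(
    net: VascularNetwork,
    proximal_ids,
    resistance_factor: float = 1.1,
    compliance_factor: float = 0.5,
    beta_factor_proximal: float = 2.5,
    beta_factor_other: float = 1.5,
) -> VascularNetwork:
    """Re-parametrize a network to represent normal ageing.

    Wall stiffness beta is increased by ``beta_factor_proximal`` on the
    declared proximal-aorta/major-branch segments and by
    ``beta_factor_other`` elsewhere; the WK3 peripheral resistances are
    scaled so the total input resistance rises by ``resistance_factor``;
    the WK3 compliances are rescaled so the total arterial compliance
    (WK + integrated 1D) falls by 1/``compliance_factor``.
    """
    from .method1 import input_resistance

    wk3s = [b for b in net.boundaries if b.variant == "wk3"]
    if not wk3s:
        raise ValidationError("ageing requires WK3 outlets")
    proximal = set(proximal_ids)
    unknown = proximal - {s.id for s in net.segments}
    if unknown:
        raise ValidationError(f"unknown proximal segment ids {sorted(unknown)}")

    C_target = compliance_factor * net.total_compliance()
    R_target = resistance_factor * input_resistance(net)

    aged = net.copy()
    aged.segments = [
        dataclasses.replace(
            s,
            beta_scale=s.beta_scale * (
                beta_factor_proximal if s.id in proximal else beta_factor_other
            ),
        )
        for s in aged.segments
    ]

    base_R2 = {b.node: b.params["R2"] for b in aged.boundaries
               if b.variant == "wk3"}

    def with_r2_scale(scale):
        trial = aged.copy()
        for b in trial.boundaries:
            if b.variant == "wk3":
                b.params["R2"] = base_R2[b.node] * scale
        return trial

    def gap(scale):
        return input_resistance(with_r2_scale(scale)) - R_target

    scale = brentq(gap, 0.5, 5.0, xtol=1e-12, rtol=1e-14)
    aged = with_r2_scale(scale)

    C_wk_needed = C_target - aged.total_1d_compliance()
    C_wk_base = aged.total_wk_compliance()
    if C_wk_needed <= 0:
        raise ValidationError(
            "stiffened 1D compliance already exceeds the compliance target"
        )
    u = C_wk_needed / C_wk_base
    for b in aged.boundaries:
        if b.variant == "wk3":
            b.params["C"] *= u
        elif b.variant == "wk_cor":
            b.params["C_a"] *= u
            b.params["C_m"] *= u
    return aged


def insert_coarctation(
    net: VascularNetwork,
    segment_id: str,
    length_s: float = 1.0,
    diameter_fraction: float = 0.5,
) -> VascularNetwork:
    """Insert a focal stenosis at the midpoint of a segment.

    The minimal area is (diameter_fraction)^2 times the local unobstructed
    area; loss coefficients follow the default empirical rule and are
    stored explicitly so they can be overridden.
    """
    seg = net.segment(segment_id)
    if length_s >= seg.length:
        raise ValidationError(
            f"stenosis length {length_s} cm >= segment length {seg.length} cm"
        )
    if not (0 < diameter_fraction <= 1):
        raise ValidationError("diameter_fraction must be in (0, 1]")
    A0 = float(seg.area_d(0.5))
    As = diameter_fraction**2 * A0
    K_visc, K_exp = young_tsai_coefficients(A0, As, length_s, net.blood)
    out = net.copy()
    out.stenoses.append(
        StenosisDescriptor(
            segment_id=segment_id,
            x_start=(seg.length - length_s) / 2.0,
            length_s=length_s,
            A0=A0,
            As=As,
            K_visc=K_visc,
            K_exp=K_exp,
        )
    )
    out.validate()
    return out


def rescale_inflow(
    wave: PeriodicWaveform, HR: float, ET: float, SV: float
) -> PeriodicWaveform:
    """Rescale an inflow waveform to a new heart rate / ejection time /
    stroke volume.

    The contiguous positive-flow support containing the cycle maximum is
    identified as the ejection interval, time-scaled to ET, and its
    amplitude scaled so the integral over one period equals SV; flow is
    zero outside ejection.  The new period is 60/HR and ejection starts at
    t = 0.
    """
    T_new = 60.0 / HR
    if ET >= T_new:
        raise ValidationError("ejection time must be shorter than the period")
    v = wave.values
    n = len(v)
    i_pk = int(np.argmax(v))
    if v[i_pk] <= 0:
        raise ValidationError("inflow waveform has no positive ejection")
    thresh = 1e-6 * v[i_pk]
    # walk outward (periodically) from the peak to the support edges
    i0 = i_pk
    while v[(i0 - 1) % n] > thresh and (i_pk - i0) < n:
        i0 -= 1
    i1 = i_pk
    while v[(i1 + 1) % n] > thresh and (i1 - i_pk) < n:
        i1 += 1
    sup = np.arange(i0, i1 + 1) % n
    ts = wave.t[sup[0]] + np.arange(len(sup)) * wave.dt
    vs = v[sup]
    # pad with the zero-flow edges so the ejection onset/offset are kept
    ts = np.concatenate([[ts[0] - wave.dt], ts, [ts[-1] + wave.dt]])
    vs = np.concatenate([[0.0], vs, [0.0]])
    t_new = np.arange(n) * (T_new / n)
    eject = t_new <= ET
    # map [0, ET] onto the source support
    src_t = ts[0] + (ts[-1] - ts[0]) * np.clip(t_new / ET, 0.0, 1.0)
    q = np.where(eject, np.interp(src_t, ts, vs), 0.0)
    integral = float(np.sum(q) * (T_new / n))
    if integral <= 0:
        raise ValidationError("rescaled waveform has no volume")
    out = PeriodicWaveform(t_new, q * (SV / integral), T_new)
    return out


def set_hyperaemia(
    net: VascularNetwork,
    alpha_healthy: float = 3.0,
    alpha_diseased: float = 1.25,
    diseased_outlets=(),
) -> VascularNetwork:
    """Divide coronary outlet resistances by the hyperaemia factor alpha.

    ``diseased_outlets`` lists the boundary nodes distal of the stenosis,
    which dilate less (alpha_diseased); all other coronary outlets use
    alpha_healthy.
    """
    cor_nodes = {b.node for b in net.boundaries if b.variant == "wk_cor"}
    if not cor_nodes:
        raise ValidationError("no coronary outlets in the network")
    unknown = set(diseased_outlets) - cor_nodes
    if unknown:
        raise ValidationError(f"unknown coronary outlets {sorted(unknown)}")
    out = net.copy()
    for b in out.boundaries:
        if b.variant != "wk_cor":
            continue
        alpha = alpha_diseased if b.node in diseased_outlets else alpha_healthy
        for key in ("R_a", "R_m", "R_v_out"):
            b.params[key] /= alpha
        b.params["alpha"] = alpha
    return out


def distribute_coronary_outlet_params(
    CO: float,
    mean_Pp: float,
    P_out: float,
    outlet_radii: dict,
    coronary_fraction: float = 0.045,
    total_compliance: float = 1e-5,
    murray_exponent: float = 3.0,
) -> dict:
    """Per-outlet (R_total, C_total) for the coronary bed.

    The total coronary resistance is (mean_Pp - P_out)/(fraction * CO);
    outlet flows follow Murray's law (Q_i proportional to r_i^exponent),
    so resistances scale as r^-exponent and compliances as r^exponent.
    """
    if any(r <= 0 for r in outlet_radii.values()):
        raise ValidationError("outlet radii must be positive")
    Q_cor = coronary_fraction * CO
    R_tot = (mean_Pp - P_out) / Q_cor
    weights = {k: r**murray_exponent for k, r in outlet_radii.items()}
    wsum = sum(weights.values())
    return {
        k: (R_tot * wsum / w, total_compliance * w / wsum)
        for k, w in weights.items()
    }
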