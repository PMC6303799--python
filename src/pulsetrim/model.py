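"""Domain types and constitutive relations for arterial networks.

An arterial network is a directed graph of tapered elastic segments joined
at junction nodes, with one inflow boundary and Windkessel-type outflow
boundaries at every terminal end.  The vessel wall obeys a thin-walled tube
law P = P_dia + (beta/A_d)(sqrt(A) - sqrt(A_d)) whose stiffness beta is set
from an empirical radius-dependent wall law through the diastolic pulse wave
velocity c_d^2 = (2/(3 rho)) * (k1*exp(k2*r_d) + k3).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .units import MMHG

__all__ = [
    "BloodProperties",
    "WallLaw",
    "SYSTEMIC_WALL_LAW",
    "CORONARY_WALL_LAW",
    "ArterialSegment",
    "StenosisDescriptor",
    "BoundaryCondition",
    "PeriodicWaveform",
    "VascularNetwork",
    "ValidationError",
    "wave_speed",
    "tube_law",
    "tube_law_area",
    "segment_viscous_resistance",
    "segment_volume_compliance",
    "young_tsai_coefficients",
]


class ValidationError(ValueError):
    """A network or component violates a structural invariant."""


@dataclass(frozen=True)
class BloodProperties:
    """Blood density, viscosity and the velocity-profile order zeta.

    zeta enters the momentum friction term f = -2(zeta+2)*pi*mu*U; zeta=9
    corresponds to a blunt velocity profile typical of large arteries.
    """

    rho: float = 1.06   # g/cm^3
    mu: float = 0.035   # g/(cm s) = poise
    zeta: float = 9.0   # dimensionless

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValidationError("rho and mu must be positive")
        if self.zeta < 2:
            raise ValidationError("zeta must be >= 2")

    @property
    def friction_factor(self) -> float:
        """2(zeta+2), the coefficient of pi*mu*U in the friction term."""
        return 2.0 * (self.zeta + 2.0)


@dataclass(frozen=True)
class WallLaw:
    """Empirical wall-stiffness law Eh/r_d = k1*exp(k2*r_d) + k3."""

    k1: float
    k2: float
    k3: float
    kind: str = "systemic"  # "systemic" | "coronary"

    def eh(self, r_d: float) -> float:
        """Elastic modulus times wall thickness, E*h (g/s^2)."""
        val = r_d * (self.k1 * math.exp(self.k2 * r_d) + self.k3)
        if val <= 0:
            raise ValidationError(
                f"wall law gives non-positive Eh at r_d={r_d!r}"
            )
        return val


SYSTEMIC_WALL_LAW = WallLaw(k1=3.0e6, k2=-9.0, k3=33.7e4, kind="systemic")
CORONARY_WALL_LAW = WallLaw(k1=20.0e6, k2=-22.5, k3=86.5e4, kind="coronary")

_WALL_LAWS = {"systemic": SYSTEMIC_WALL_LAW, "coronary": CORONARY_WALL_LAW}


def wall_law_by_name(name: str) -> WallLaw:
    try:
        return _WALL_LAWS[name]
    except KeyError:
        raise ValidationError(f"unknown wall law {name!r}") from None


def wave_speed(r_d: float, law: WallLaw, blood: BloodProperties) -> float:
    """Diastolic pulse wave velocity c_d (cm/s) at radius r_d (cm).

    c_d = sqrt( (2/(3 rho)) * (k1*exp(k2*r_d) + k3) ).
    """
    if r_d <= 0:
        raise ValidationError("r_d must be positive")
    radicand = 2.0 / (3.0 * blood.rho) * (law.k1 * math.exp(law.k2 * r_d) + law.k3)
    if radicand <= 0:
        raise ValidationError("unphysical wall law: non-positive c_d^2")
    return math.sqrt(radicand)


@dataclass(frozen=True)
class ArterialSegment:
    """One tapered 1D vessel segment.

    Radius tapers linearly from r_prox_dia to r_dist_dia along the length.
    ``beta_override``, when given, fixes the tube-law stiffness directly
    (uniform along the segment) instead of deriving it from the wall law.
    """

    id: str
    length: float          # cm
    r_prox_dia: float      # cm
    r_dist_dia: float      # cm
    wall_law: WallLaw = SYSTEMIC_WALL_LAW
    p_dia_ref: float = 80.0 * MMHG  # dyn/cm^2
    name: str = ""
    beta_override: float | None = None  # g s^-2 cm^-1
    beta_scale: float = 1.0  # multiplicative stiffening (ageing scenarios)

    def __post_init__(self):
        if self.length <= 0:
            raise ValidationError(f"segment {self.id}: length must be > 0")
        if self.r_prox_dia <= 0 or self.r_dist_dia <= 0:
            raise ValidationError(f"segment {self.id}: radii must be > 0")

    def r_d(self, s):
        """Diastolic radius at relative position s in [0, 1]."""
        return self.r_prox_dia + (self.r_dist_dia - self.r_prox_dia) * np.asarray(s)

    def area_d(self, s):
        """Diastolic cross-sectional area at relative position s."""
        r = self.r_d(s)
        return np.pi * r * r

    def beta(self, s):
        """Tube-law stiffness beta(x) = (4/3) sqrt(pi) E h (times beta_scale)."""
        if self.beta_override is not None:
            out = self.beta_scale * self.beta_override * np.ones_like(
                np.asarray(s, dtype=float)
            )
        else:
            r = np.atleast_1d(np.asarray(self.r_d(s), dtype=float))
            eh = r * (
                self.wall_law.k1 * np.exp(self.wall_law.k2 * r) + self.wall_law.k3
            )
            out = self.beta_scale * (4.0 / 3.0) * math.sqrt(math.pi) * eh
        if np.asarray(s).ndim == 0:
            return float(np.atleast_1d(out)[0])
        return np.broadcast_to(out, np.asarray(s).shape).copy()


def tube_law(A, segment: ArterialSegment, s=0.5, blood: BloodProperties | None = None):
    """Transmural pressure from area: P = P_dia + (beta/A_d)(sqrt(A)-sqrt(A_d))."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValidationError("area must be positive")
    A_d = segment.area_d(s)
    beta = segment.beta(s)
    out = segment.p_dia_ref + beta / A_d * (np.sqrt(A) - np.sqrt(A_d))
    return float(out) if out.ndim == 0 else out


def tube_law_area(P, segment: ArterialSegment, s=0.5):
    """Inverse of :func:`tube_law`: area at pressure P (exact above collapse)."""
    P = np.asarray(P, dtype=float)
    A_d = segment.area_d(s)
    beta = segment.beta(s)
    root = np.sqrt(A_d) + (P - segment.p_dia_ref) * A_d / beta
    if np.any(root <= 0):
        raise ValidationError("pressure below collapse: tube law not invertible")
    out = root * root
    return float(out) if out.ndim == 0 else out


def segment_viscous_resistance(
    segment: ArterialSegment,
    blood: BloodProperties,
    area_profile=None,
    n_quad: int = 101,
) -> float:
    """Poiseuille-type viscous resistance R_v = int 2(zeta+2) pi mu / A(x)^2 dx.

    ``area_profile`` is an optional callable s -> area (cm^2) giving the
    linearization state; the diastolic area profile is used by default.
    Composite-trapezoid quadrature along the taper.
    """
    s = np.linspace(0.0, 1.0, n_quad)
    A = segment.area_d(s) if area_profile is None else np.asarray(area_profile(s), float)
    integrand = blood.friction_factor * math.pi * blood.mu / (A * A)
    return float(np.trapezoid(integrand, s * segment.length))


def segment_volume_compliance(
    segment: ArterialSegment,
    blood: BloodProperties,
    area_profile=None,
    n_quad: int = 101,
) -> float:
    """Volume compliance C_v = (1/rho) int A(x)/c(x)^2 dx of one segment."""
    s = np.linspace(0.0, 1.0, n_quad)
    A_d = segment.area_d(s)
    beta = segment.beta(s)
    A = A_d if area_profile is None else np.asarray(area_profile(s), float)
    # c(A)^2 = beta sqrt(A) / (2 rho A_d), from the tube law
    c2 = beta * np.sqrt(A) / (2.0 * blood.rho * A_d)
    integrand = A / c2
    return float(np.trapezoid(integrand, s * segment.length) / blood.rho)


@dataclass(frozen=True)
class StenosisDescriptor:
    """Empirical stenosis: pressure loss dP = K_visc*Q + K_exp*Q|Q|.

    The stenotic span [x_start, x_start+length_s] is removed from the 1D
    grid and replaced by a two-way junction carrying the loss.
    """

    segment_id: str
    x_start: float    # cm from proximal end
    length_s: float   # cm
    A0: float         # unobstructed area, cm^2
    As: float         # minimal area, cm^2
    K_visc: float     # dyn s / cm^5
    K_exp: float      # dyn s^2 / cm^8

    def __post_init__(self):
        if not (0 < self.As <= self.A0):
            raise ValidationError(
                f"stenosis on {self.segment_id}: need 0 < As <= A0 "
                f"(got As={self.As}, A0={self.A0})"
            )
        if self.K_visc < 0 or self.K_exp < 0:
            raise ValidationError("stenosis coefficients must be >= 0")

    def pressure_loss(self, Q):
        return self.K_visc * Q + self.K_exp * Q * np.abs(Q)


def young_tsai_coefficients(
    A0: float, As: float, length_s: float, blood: BloodProperties
) -> tuple[float, float]:
    """Default empirical stenosis coefficients (Young & Tsai type rule).

    K_visc = Kv * mu / (A0 * D0) with Kv = 32 (0.83 L_s + 1.64 D_s) (A0/As)^2 / D0,
    K_exp  = Kt * rho / (2 A0^2) * (A0/As - 1)^2 with Kt = 1.52.

    Returned values can be overridden field-by-field in the network file.
    """
    D0 = 2.0 * math.sqrt(A0 / math.pi)
    Ds = 2.0 * math.sqrt(As / math.pi)
    Kv = 32.0 * (0.83 * length_s + 1.64 * Ds) * (A0 / As) ** 2 / D0
    K_visc = Kv * blood.mu / (A0 * D0)
    Kt = 1.52
    K_exp = Kt * blood.rho / (2.0 * A0 * A0) * (A0 / As - 1.0) ** 2
    return K_visc, K_exp


@dataclass
class PeriodicWaveform:
    """Uniformly sampled periodic signal over one period.

    The grid excludes the wrap point: t = 0, dt, ..., T - dt, so that
    values[0] is also the sample at t = T.
    """

    t: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape or self.t.ndim != 1:
            raise ValidationError("t and values must be 1D arrays of equal length")
        if self.period <= 0:
            raise ValidationError("period must be positive")
        dt = np.diff(self.t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValidationError("waveform grid must be uniform")
        if self.t[-1] >= self.period:
            raise ValidationError("grid must exclude the wrap point t = period")

    @property
    def dt(self) -> float:
        return self.period / len(self.t)

    def __call__(self, t):
        """Periodic linear interpolation at arbitrary times."""
        tq = np.mod(np.asarray(t, dtype=float), self.period)
        tp = np.concatenate([self.t, [self.period]])
        vp = np.concatenate([self.values, [self.values[0]]])
        out = np.interp(tq, tp, vp)
        return float(out) if out.ndim == 0 else out

    def mean(self) -> float:
        return float(np.mean(self.values))

    def integral(self) -> float:
        """Integral over one period (trapezoid with periodic wrap)."""
        return float(np.sum(self.values) * self.dt)

    def resample(self, n: int) -> "PeriodicWaveform":
        t = np.arange(n) * self.period / n
        return PeriodicWaveform(t, self(t), self.period)


@dataclass
class BoundaryCondition:
    """Boundary attached to a terminal segment end.

    variants:
      inflow_Q : prescribed periodic flow waveform
      inflow_P : prescribed periodic pressure waveform
      wk3      : three-element Windkessel (R1, C, R2, P_out)
      wk_cor   : coronary Windkessel
                 (R_a, C_a, R_m, C_m, R_v_out, gamma_im, lv_pressure, alpha)
    """

    node: str
    variant: str
    params: dict = field(default_factory=dict)

    _REQUIRED = {
        "inflow_Q": ("waveform",),
        "inflow_P": ("waveform",),
        "wk3": ("R1", "C", "R2", "P_out"),
        "wk_cor": ("R_a", "C_a", "R_m", "C_m", "R_v_out", "P_out",
                   "gamma_im", "lv_pressure", "alpha"),
    }

    def __post_init__(self):
        if self.variant not in self._REQUIRED:
            raise ValidationError(f"unknown boundary variant {self.variant!r}")
        missing = [k for k in self._REQUIRED[self.variant] if k not in self.params]
        if missing:
            raise ValidationError(
                f"boundary at {self.node}: missing params {missing}"
            )
        p = self.params
        if self.variant == "wk3":
            if p["R1"] <= 0 or p["R2"] <= 0 or p["C"] <= 0:
                raise ValidationError(
                    f"boundary at {self.node}: WK3 resistances/compliance must be > 0"
                )
        if self.variant == "wk_cor":
            for k in ("R_a", "R_m", "R_v_out", "C_a", "C_m"):
                if p[k] <= 0:
                    raise ValidationError(
                        f"boundary at {self.node}: coronary {k} must be > 0"
                    )
            if p["alpha"] < 1:
                raise ValidationError("hyperaemia divisor alpha must be >= 1")

    @property
    def is_inflow(self) -> bool:
        return self.variant in ("inflow_Q", "inflow_P")

    @property
    def total_resistance(self) -> float:
        """Series resistance of the outlet (steady state)."""
        p = self.params
        if self.variant == "wk3":
            return p["R1"] + p["R2"]
        if self.variant == "wk_cor":
            return p["R_a"] + p["R_m"] + p["R_v_out"]
        raise ValidationError("inflow boundary has no outlet resistance")


@dataclass
class VascularNetwork:
    """Directed graph of arterial segments.

    ``topology`` maps node name -> list of (segment_id, end) with end in
    {"prox", "dist"}.  Every segment appears exactly twice (once per end).
    Terminal nodes (degree 1) carry exactly one boundary condition; internal
    nodes are junctions (degree >= 2).  Loops are permitted.
    """

    segments: list[ArterialSegment]
    topology: dict[str, list[tuple[str, str]]]
    stenoses: list[StenosisDescriptor] = field(default_factory=list)
    boundaries: list[BoundaryCondition] = field(default_factory=list)
    blood: BloodProperties = field(default_factory=BloodProperties)

    def __post_init__(self):
        self.validate()

    # -- structure helpers -------------------------------------------------
    def segment(self, seg_id: str) -> ArterialSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    def node_of(self, seg_id: str, end: str) -> str:
        for node, ports in self.topology.items():
            if (seg_id, end) in [tuple(p) for p in ports]:
                return node
        raise KeyError((seg_id, end))

    def boundary_at(self, node: str) -> BoundaryCondition | None:
        for b in self.boundaries:
            if b.node == node:
                return b
        return None

    @property
    def inflow_boundary(self) -> BoundaryCondition:
        return next(b for b in self.boundaries if b.is_inflow)

    @property
    def inflow_node(self) -> str:
        return self.inflow_boundary.node

    def terminal_nodes(self) -> list[str]:
        return [n for n, ports in self.topology.items() if len(ports) == 1]

    def junction_nodes(self) -> list[str]:
        return [n for n, ports in self.topology.items() if len(ports) >= 2]

    def stenoses_on(self, seg_id: str) -> list[StenosisDescriptor]:
        return [st for st in self.stenoses if st.segment_id == seg_id]

    def as_graph(self):
        """networkx MultiGraph of nodes with segment-id edge keys."""
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(self.topology)
        for seg in self.segments:
            g.add_edge(
                self.node_of(seg.id, "prox"),
                self.node_of(seg.id, "dist"),
                key=seg.id,
            )
        return g

    def copy(self) -> "VascularNetwork":
        return copy.deepcopy(self)

    # -- validation --------------------------------------------------------
    def validate(self):
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate segment ids")
        ends = {}
        for node, ports in self.topology.items():
            for seg_id, end in (tuple(p) for p in ports):
                if seg_id not in ids:
                    raise ValidationError(
                        f"topology references unknown segment {seg_id!r}"
                    )
                if end not in ("prox", "dist"):
                    raise ValidationError(f"bad end tag {end!r} on {seg_id}")
                if (seg_id, end) in ends:
                    raise ValidationError(f"({seg_id}, {end}) attached twice")
                ends[(seg_id, end)] = node
        for sid in ids:
            for end in ("prox", "dist"):
                if (sid, end) not in ends:
                    raise ValidationError(
                        f"segment {sid}: {end} end not attached to a node"
                    )
        g = self.as_graph()
        import networkx as nx

        if len(self.segments) and not nx.is_connected(g):
            raise ValidationError("network is not connected")

        inflows = [b for b in self.boundaries if b.is_inflow]
        if len(inflows) != 1:
            raise ValidationError(
                f"exactly one inflow boundary required (found {len(inflows)})"
            )
        term = set(self.terminal_nodes())
        bc_nodes = [b.node for b in self.boundaries]
        if len(set(bc_nodes)) != len(bc_nodes):
            raise ValidationError("multiple boundary conditions on one node")
        for b in self.boundaries:
            if b.node not in term:
                raise ValidationError(
                    f"boundary at {b.node!r} is not on a terminal node"
                )
        missing = term - set(bc_nodes)
        if missing:
            raise ValidationError(
                f"terminal nodes without boundary condition: {sorted(missing)}"
            )
        for st in self.stenoses:
            seg = self.segment(st.segment_id)
            if st.x_start < 0 or st.x_start + st.length_s > seg.length:
                raise ValidationError(
                    f"stenosis span outside segment {st.segment_id}"
                )
        # wall law must give positive stiffness everywhere
        for seg in self.segments:
            for s in (0.0, 1.0):
                if seg.beta_override is None:
                    seg.wall_law.eh(float(seg.r_d(s)))

    # -- derived whole-network quantities ----------------------------------
    def total_1d_compliance(self) -> float:
        """Sum of diastolic-state volume compliances of all segments."""
        return sum(
            segment_volume_compliance(s, self.blood) for s in self.segments
        )

    def total_wk_compliance(self) -> float:
        tot = 0.0
        for b in self.boundaries:
            if b.variant == "wk3":
                tot += b.params["C"]
            elif b.variant == "wk_cor":
                tot += b.params["C_a"] + b.params["C_m"]
        return tot

    def total_compliance(self) -> float:
        """Total arterial compliance: WK compliances + integrated 1D compliance."""
        return self.total_1d_compliance() + self.total_wk_compliance()


def replace_boundary(net: VascularNetwork, node: str, new_bc: BoundaryCondition):
    """Pure helper: return a copy of the network with one boundary swapped."""
    out = net.copy()
    out.boundaries = [new_bc if b.node == node else b for b in out.boundaries]
    return out
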