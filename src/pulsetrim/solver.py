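"""Explicit MacCormack solver for 1D pulse-wave propagation on a network.

The conservation form solved per segment is

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx = -(A/rho) dP/dx + f/rho,   f = -2(zeta+2) pi mu U

with P = P(A; x) from the tube law.  Vessel ends are coupled at junctions by
conservation of mass and continuity of total pressure, closed with the
outgoing Riemann invariants W+- = U +- 4c extrapolated first-order along the
characteristics from the interior.  Stenotic spans are removed from the grid
and represented as two-way junctions with an empirical pressure loss.
Outlets are three-element Windkessel (WK3) or coronary Windkessel chains
integrated with the Crank-Nicolson rule inside the boundary Newton solve.

The solver marches whole cardiac cycles until the cycle-to-cycle relative
L2 change of pressure at every output site falls below ``periodicity_tol``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    BoundaryCondition,
    PeriodicWaveform,
    StenosisDescriptor,
    ValidationError,
    VascularNetwork,
)

__all__ = [
    "SolverConfig",
    "SimulationResult",
    "SolverError",
    "run_simulation",
    "stenosis_pressure_loss",
    "wk3_outlet_step",
    "wkcor_outlet_step",
]

N_OUTPUT = 1000  # uniform output samples per cycle


class SolverError(RuntimeError):
    pass



@dataclass
class SolverConfig:
    dx_target: float = 0.25       # cm
    cfl: float = 0.9
    max_cycles: int = 20
    periodicity_tol: float = 1e-3
    output_sites: list = field(default_factory=list)  # [(segment_id, rel pos)]
    dt_override: float | None = None

    def __post_init__(self):
        if not (0 < self.cfl <= 1):
            raise ValidationError("cfl must be in (0, 1]")
        if self.dx_target <= 0 or self.periodicity_tol <= 0:
            raise ValidationError("dx_target and periodicity_tol must be > 0")


@dataclass
class SimulationResult:
    """Converged-cycle waveforms at the requested sites.

    ``sites`` maps (segment_id, position) -> dict with PeriodicWaveform
    entries "P", "Q", "A" on a uniform 1000-point grid over one cycle.
    """

    sites: dict
    period: float
    cycles_run: int
    converged: bool
    periodicity_residual: float
    max_junction_mass_defect: float = 0.0
    dt: float = 0.0

    def waveform(self, segment_id, position, var="P") -> PeriodicWaveform:
        key = self._resolve(segment_id, position)
        return self.sites[key][var]

    def _resolve(self, segment_id, position):
        if (segment_id, position) in self.sites:
            return (segment_id, position)
        cands = [k for k in self.sites if k[0] == segment_id]
        if not cands:
            raise KeyError(f"no output site on segment {segment_id!r}")
        return min(cands, key=lambda k: abs(k[1] - position))


# ---------------------------------------------------------------------------
# standalone lumped-element steps (also used inside the boundary solves)

def stenosis_pressure_loss(Q, sten: StenosisDescriptor):
    """Empirical trans-stenotic loss dP = K_visc*Q + K_exp*Q|Q|."""
    return sten.pressure_loss(Q)


def wk3_outlet_step(Q_old, Q_new, P_c, R1, C, R2, P_out, dt):
    """One Crank-Nicolson step of the WK3 ODE C dP_c/dt = Q - (P_c-P_out)/R2.

    Returns (P, P_c_new) where P = P_c_new + R1*Q_new is the coupling
    pressure seen by the 1D domain.
    """
    kappa = dt / (2.0 * R2 * C)
    P_c_new = (
        P_c * (1.0 - kappa)
        + dt / (2.0 * C) * (Q_old + Q_new)
        + 2.0 * kappa * P_out
    ) / (1.0 + kappa)
    return P_c_new + R1 * Q_new, P_c_new


def _wkcor_matrices(params, dt):
    R_m, R_v = params["R_m"], params["R_v_out"]
    C_a, C_m = params["C_a"], params["C_m"]
    M = np.array(
        [
            [-1.0 / (R_m * C_a), 1.0 / (R_m * C_a)],
            [1.0 / (R_m * C_m), -(1.0 / R_m + 1.0 / R_v) / C_m],
        ]
    )
    S = np.eye(2) - 0.5 * dt * M
    T = np.eye(2) + 0.5 * dt * M
    return M, S, T


def _wkcor_b0(params, P_lv_t):
    """Forcing term excluding the inflow Q (state x = (P_a, v), v = P_m - g*P_lv)."""
    g = params["gamma_im"]
    R_m, R_v = params["R_m"], params["R_v_out"]
    C_a, C_m = params["C_a"], params["C_m"]
    gl = g * P_lv_t
    return np.array(
        [
            gl / (R_m * C_a),
            (-gl / R_m - (gl - params["P_out"]) / R_v) / C_m,
        ]
    )


def wkcor_outlet_step(Q_old, Q_new, state, params, P_lv_old, P_lv_new, dt):
    """Crank-Nicolson step of the coronary Windkessel chain.

    Topology: 1D end --R_a--> (C_a to P_out) --R_m--> (C_m to gamma*P_lv)
    --R_v_out--> P_out.  ``state`` is (P_a, v) with v = P_m - gamma*P_lv.
    Returns (P, new_state) with P = P_a_new + R_a*Q_new.
    """
    state = np.asarray(state, dtype=float)
    _, S, T = _wkcor_matrices(params, dt)
    b_old = _wkcor_b0(params, P_lv_old)
    b_old[0] += Q_old / params["C_a"]
    b_new = _wkcor_b0(params, P_lv_new)
    b_new[0] += Q_new / params["C_a"]
    rhs = T @ state + 0.5 * dt * (b_old + b_new)
    new = np.linalg.solve(S, rhs)
    return new[0] + params["R_a"] * Q_new, new


# ---------------------------------------------------------------------------
# grid construction

class _Piece:
    """A contiguous 1D grid piece (a segment or part of a split segment)."""

    __slots__ = (
        "seg", "s0", "s1", "n", "dx", "i0", "i1", "x_abs0",
    )

    def __init__(self, seg, s0, s1, dx_target):
        self.seg = seg
        self.s0, self.s1 = s0, s1
        length = (s1 - s0) * seg.length
        if length < dx_target / 2:
            raise SolverError(
                f"grid piece of segment {seg.id} is shorter than dx/2; "
                "move the stenosis or refine dx_target"
            )
        self.n = max(2, int(round(length / dx_target)) + 1)
        self.dx = length / (self.n - 1)


class _WK3State:
    def __init__(self, bc, P_init):
        p = bc.params
        self.R1, self.C, self.R2 = p["R1"], p["C"], p["R2"]
        self.P_out = p["P_out"]
        self.P_c = P_init

    def precompute(self, dt, Q_old):
        kappa = dt / (2.0 * self.R2 * self.C)
        self.dPdQ = (dt / (2.0 * self.C)) / (1.0 + kappa)
        self.P0 = (
            self.P_c * (1.0 - kappa)
            + dt / (2.0 * self.C) * Q_old
            + 2.0 * kappa * self.P_out
        ) / (1.0 + kappa)

    # P_c^{n+1} = P0 + dPdQ * Q_new
    def commit(self, Q_new):
        self.P_c = self.P0 + self.dPdQ * Q_new


class _WKCorState:
    def __init__(self, bc, P_init):
        self.params = bc.params
        lv = self.params["lv_pressure"]
        g = self.params["gamma_im"]
        self.lv = lv
        self.R1 = self.params["R_a"]  # proximal resistance seen by the 1D end
        self.x = np.array([P_init, P_init - g * lv(0.0)])

    def precompute(self, dt, Q_old, t_old, t_new):
        p = self.params
        _, S, T = _wkcor_matrices(p, dt)
        b_old = _wkcor_b0(p, self.lv(t_old))
        b_old[0] += Q_old / p["C_a"]
        b_new0 = _wkcor_b0(p, self.lv(t_new))
        Sinv = np.linalg.inv(S)
        self.X0 = Sinv @ (T @ self.x + 0.5 * dt * (b_old + b_new0))
        self.XQ = Sinv @ np.array([0.5 * dt / p["C_a"], 0.0])
        self.P0 = self.X0[0]
        self.dPdQ = self.XQ[0]

    def commit(self, Q_new):
        self.x = self.X0 + Q_new * self.XQ


class _Port:
    """One vessel end participating in a junction or boundary."""

    __slots__ = ("idx", "nbr", "sign", "dx", "A_d", "beta", "p_dia")

    def __init__(self, piece, end, A_d, beta, p_dia):
        if end == "dist":
            self.idx = piece.i1 - 1
            self.nbr = piece.i1 - 2
            self.sign = +1.0
        else:
            self.idx = piece.i0
            self.nbr = piece.i0 + 1
            self.sign = -1.0
        self.dx = piece.dx
        self.A_d = A_d[self.idx]
        self.beta = beta[self.idx]
        self.p_dia = p_dia[self.idx]


class _Grid:
    def __init__(self, net: VascularNetwork, config: SolverConfig):
        self.net = net
        self.blood = net.blood
        pieces = []
        piece_map = {}  # seg_id -> list of (piece, s0, s1)
        for seg in net.segments:
            stens = sorted(net.stenoses_on(seg.id), key=lambda st: st.x_start)
            cuts = [0.0]
            for st in stens:
                cuts += [st.x_start / seg.length,
                         (st.x_start + st.length_s) / seg.length]
            cuts.append(1.0)
            segs_pieces = []
            for k in range(0, len(cuts), 2):
                p = _Piece(seg, cuts[k], cuts[k + 1], config.dx_target)
                pieces.append(p)
                segs_pieces.append(p)
            piece_map[seg.id] = (segs_pieces, stens)
        # global node numbering
        off = 0
        for p in pieces:
            p.i0, p.i1 = off, off + p.n
            off += p.n
        self.n_nodes = off
        self.pieces = pieces
        self.piece_map = piece_map

        # per-node geometry
        A_d = np.empty(off)
        beta = np.empty(off)
        p_dia = np.empty(off)
        dx = np.empty(off)
        for p in pieces:
            s = np.linspace(p.s0, p.s1, p.n)
            A_d[p.i0:p.i1] = p.seg.area_d(s)
            beta[p.i0:p.i1] = p.seg.beta(s)
            p_dia[p.i0:p.i1] = p.seg.p_dia_ref
            dx[p.i0:p.i1] = p.dx
        self.A_d, self.beta, self.p_dia, self.dx = A_d, beta, p_dia, dx
        self.sqrt_A_d = np.sqrt(A_d)
        self.last_mask = np.zeros(off, dtype=bool)
        self.first_mask = np.zeros(off, dtype=bool)
        for p in pieces:
            self.last_mask[p.i1 - 1] = True
            self.first_mask[p.i0] = True

        self._build_couplings(config)
        self._resolve_sites(config)

    # -- couplings ---------------------------------------------------------
    def _build_couplings(self, config):
        net = self.net
        make_port = lambda piece, end: _Port(
            piece, end, self.A_d, self.beta, self.p_dia
        )
        junctions = []  # (name, [ports], dP_coeffs or None, up_port_index)
        boundaries = []  # (bc, port)
        for node, ports in net.topology.items():
            ends = []
            for seg_id, end in (tuple(p) for p in ports):
                segs_pieces, _ = self.piece_map[seg_id]
                piece = segs_pieces[0] if end == "prox" else segs_pieces[-1]
                ends.append(make_port(piece, end))
            bc = net.boundary_at(node)
            if bc is not None:
                if len(ends) != 1:
                    raise SolverError(
                        f"boundary node {node} must attach exactly one segment"
                    )
                boundaries.append((bc, ends[0]))
            else:
                if len(ends) < 2:
                    raise SolverError(f"dangling node {node} without boundary")
                junctions.append((node, ends, None))
        # internal stenosis junctions
        for seg_id, (segs_pieces, stens) in self.piece_map.items():
            for k, st in enumerate(stens):
                up = make_port(segs_pieces[k], "dist")
                dn = make_port(segs_pieces[k + 1], "prox")
                junctions.append((f"{seg_id}:stenosis{k}", [up, dn], st))
        self.junctions = junctions
        self.boundaries = boundaries

    # -- output sites --------------------------------------------------------
    def node_at(self, seg_id, pos):
        segs_pieces, _ = self.piece_map[seg_id]
        target = pos
        best, best_d = None, np.inf
        for p in segs_pieces:
            s = np.linspace(p.s0, p.s1, p.n)
            j = int(np.argmin(np.abs(s - target)))
            d = abs(s[j] - target)
            if d < best_d:
                best, best_d = p.i0 + j, d
        return best

    def _resolve_sites(self, config):
        self.site_nodes = {}
        for seg_id, pos in config.output_sites:
            self.site_nodes[(seg_id, pos)] = self.node_at(seg_id, pos)


# ---------------------------------------------------------------------------
# junction / boundary Newton solves

def _wave_speed_arr(A, beta, A_d, rho):
    return np.sqrt(beta * np.sqrt(A) / (2.0 * rho * A_d))


def _solve_junction(ports, dP_sten, A, Q, rho, W_feet, tol=1e-10, max_iter=100):
    """Newton solve of the junction system; returns (A_k, u_k) per port.

    Unknowns are (A_k, u_k) for each port.  Equations: one outgoing-
    invariant match per port, mass conservation, and N-1 total-pressure
    equations with the optional stenosis loss between port 0 (upstream) and
    port 1.
    """
    n = len(ports)
    Avec = np.array([A[p.idx] for p in ports])
    uvec = np.array([Q[p.idx] / A[p.idx] for p in ports])
    beta = np.array([p.beta for p in ports])
    A_d = np.array([p.A_d for p in ports])
    p_dia = np.array([p.p_dia for p in ports])
    sgn = np.array([p.sign for p in ports])

    c_ref = float(np.max(_wave_speed_arr(Avec, beta, A_d, rho)))
    q_ref = max(float(np.max(np.abs(Avec * uvec))), 1e-6)
    p_ref = rho * c_ref * c_ref

    x = np.concatenate([Avec, uvec])
    for _ in range(max_iter):
        Ak = x[:n]
        uk = x[n:]
        ck = _wave_speed_arr(Ak, beta, A_d, rho)
        Pk = p_dia + beta / A_d * (np.sqrt(Ak) - np.sqrt(A_d))
        dPdA = beta / (2.0 * A_d * np.sqrt(Ak))
        res = np.empty(2 * n)
        jac = np.zeros((2 * n, 2 * n))
        # invariant rows
        for k in range(n):
            res[k] = uk[k] + sgn[k] * 4.0 * ck[k] - W_feet[k]
            jac[k, k] = sgn[k] * ck[k] / Ak[k]
            jac[k, n + k] = 1.0
        # mass row
        res[n] = float(np.dot(sgn, Ak * uk))
        jac[n, :n] = sgn * uk
        jac[n, n:] = sgn * Ak
        # pressure rows (k = 1..n-1): P0 + rho u0^2/2 - Pk - rho uk^2/2 - dP
        for k in range(1, n):
            r = Pk[0] + 0.5 * rho * uk[0] ** 2 - Pk[k] - 0.5 * rho * uk[k] ** 2
            row = n + k
            jac[row, 0] = dPdA[0]
            jac[row, n] = rho * uk[0]
            jac[row, k] = -dPdA[k]
            jac[row, n + k] = -rho * uk[k]
            if dP_sten is not None:
                Qthru = sgn[0] * Ak[0] * uk[0]
                r -= dP_sten.pressure_loss(Qthru)
                dloss = dP_sten.K_visc + 2.0 * dP_sten.K_exp * abs(Qthru)
                jac[row, 0] -= dloss * sgn[0] * uk[0]
                jac[row, n] -= dloss * sgn[0] * Ak[0]
            res[row] = r
        scale = np.concatenate(
            [np.full(n, c_ref), [q_ref], np.full(n - 1, p_ref)]
        )
        if np.max(np.abs(res) / scale) < tol:
            break
        try:
            dx = np.linalg.solve(jac, -res)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"junction solve failed: {exc}") from None
        x = x + dx
        x[:n] = np.maximum(x[:n], 1e-4 * A_d)
    else:
        raise SolverError("junction Newton did not converge in 100 iterations")
    mass_defect = abs(float(np.dot(sgn, x[:n] * x[n:])))
    return x[:n], x[n:], mass_defect


def _foot_value(port, A, Q, beta, A_d, rho, dt):
    """First-order characteristic extrapolation of the outgoing invariant."""
    i, j = port.idx, port.nbr
    Ai, Aj = A[i], A[j]
    ui, uj = Q[i] / Ai, Q[j] / Aj
    ci = math.sqrt(beta[i] * math.sqrt(Ai) / (2.0 * rho * A_d[i]))
    cj = math.sqrt(beta[j] * math.sqrt(Aj) / (2.0 * rho * A_d[j]))
    if port.sign > 0:  # dist end, outgoing W+ travels at u + c
        lam = max(ui + ci, 0.0)
        th = min(lam * dt / port.dx, 1.0)
        Wi, Wj = ui + 4.0 * ci, uj + 4.0 * cj
    else:  # prox end, outgoing W- travels at u - c (leftward)
        lam = max(ci - ui, 0.0)
        th = min(lam * dt / port.dx, 1.0)
        Wi, Wj = ui - 4.0 * ci, uj - 4.0 * cj
    return (1.0 - th) * Wi + th * Wj


def _solve_inflow_Q(port, Q_presc, W_foot, A_guess, beta, A_d, rho):
    """Scalar Newton for the inlet area with prescribed volumetric inflow."""
    b, ad = port.beta, port.A_d
    # segment-frame flow: inflow at a prox end is +Q, at a dist end -Q
    Qs = Q_presc if port.sign < 0 else -Q_presc
    A = A_guess
    for _ in range(100):
        c = math.sqrt(b * math.sqrt(A) / (2.0 * rho * ad))
        u = Qs / A
        res = u + port.sign * 4.0 * c - W_foot
        dres = -Qs / (A * A) + port.sign * c / A
        step = -res / dres
        A_new = A + step
        if A_new <= 0:
            A_new = 0.5 * A
        if abs(A_new - A) < 1e-14 * ad + 1e-12:
            A = A_new
            break
        A = A_new
    return A, Qs / A


def _solve_wk_outlet(port, wk, W_foot, A_guess, u_guess, rho):
    """2x2 Newton for (A, u) at a Windkessel-coupled terminal end."""
    b, ad, p_dia = port.beta, port.A_d, port.p_dia
    A, u = A_guess, u_guess
    for it in range(100):
        c = math.sqrt(b * math.sqrt(A) / (2.0 * rho * ad))
        P = p_dia + b / ad * (math.sqrt(A) - math.sqrt(ad))
        dPdA = b / (2.0 * ad * math.sqrt(A))
        Q_out = port.sign * A * u
        r1 = u + port.sign * 4.0 * c - W_foot
        r2 = P - (wk.P0 + wk.dPdQ * Q_out) - wk.R1 * Q_out
        if abs(r1) < 1e-12 * max(c, 1.0) and abs(r2) < 1e-10 * rho * c * c:
            break
        j11 = port.sign * c / A
        j12 = 1.0
        dQdA = port.sign * u
        dQdu = port.sign * A
        j21 = dPdA - (wk.dPdQ + wk.R1) * dQdA
        j22 = -(wk.dPdQ + wk.R1) * dQdu
        det = j11 * j22 - j12 * j21
        dA = -(r1 * j22 - j12 * r2) / det
        du = -(j11 * r2 - r1 * j21) / det
        A = max(A + dA, 1e-4 * ad)
        u = u + du
    return A, u


# ---------------------------------------------------------------------------

def run_simulation(net: VascularNetwork, config: SolverConfig) -> SimulationResult:
    """March the network to a periodic state and return the final cycle."""
    net.validate()
    blood = net.blood
    rho, mu = blood.rho, blood.mu
    kf = blood.friction_factor  # 2(zeta+2)

    inflow_bc = net.inflow_boundary
    wave = inflow_bc.params["waveform"]
    T = wave.period

    grid = _Grid(net, config)
    A = grid.A_d.copy()
    Q = np.zeros(grid.n_nodes)
    A_d, beta, p_dia = grid.A_d, grid.beta, grid.p_dia
    sqrt_A_d = grid.sqrt_A_d
    dx = grid.dx
    last, first = grid.last_mask, grid.first_mask

    # boundary state objects
    bstates = []
    for bc, port in grid.boundaries:
        if bc.variant == "wk3":
            bstates.append((bc, port, _WK3State(bc, p_dia[port.idx])))
        elif bc.variant == "wk_cor":
            bstates.append((bc, port, _WKCorState(bc, p_dia[port.idx])))
        else:
            bstates.append((bc, port, None))

    t_out = np.arange(N_OUTPUT) * (T / N_OUTPUT)
    prev_cycle = None
    residual = np.inf
    converged = False
    max_mass_defect = 0.0
    cycles = 0
    dt_used = 0.0

    src_coef = -kf * math.pi * mu / rho

    dt_shrink = 1.0  # accumulated safety factor after mid-cycle CFL retries
    retries = 0

    cycle = 0
    while cycle < config.max_cycles:
        cycles = cycle + 1
        # CFL time step, fixed within the cycle
        c_arr = _wave_speed_arr(A, beta, A_d, rho)
        lam = np.abs(Q / A) + c_arr
        dt_cfl = config.cfl * dt_shrink * float(np.min(dx / lam))
        dt = config.dt_override if config.dt_override else dt_cfl
        n_steps = max(int(math.ceil(T / dt)), 2)
        dt = T / n_steps
        dt_used = dt
        r = dt / dx

        # snapshot so the cycle can be redone with a smaller dt if the
        # wave speed grows past the cycle-start CFL estimate
        snap_A, snap_Q = A.copy(), Q.copy()
        snap_wk = [
            (wk.P_c if isinstance(wk, _WK3State)
             else wk.x.copy() if isinstance(wk, _WKCorState) else None)
            for _, _, wk in bstates
        ]

        rec = {key: {"P": [], "Q": [], "A": []} for key in grid.site_nodes}
        t_axis = np.empty(n_steps)
        cfl_retry = None

        for step in range(n_steps):
            t_n = step * dt
            t_np1 = (step + 1) * dt
            t_axis[step] = t_n

            # CFL sanity (state drifts within the cycle)
            c_arr = np.sqrt(beta * np.sqrt(A) / (2.0 * rho * A_d))
            courant = (np.abs(Q / A) + c_arr) * dt / dx
            imax = int(np.argmax(courant))
            if courant[imax] > 1.0 + 1e-9:
                if config.dt_override:
                    raise SolverError(
                        f"CFL violated at node {imax} "
                        f"(Courant={courant[imax]:.3f})"
                    )
                cfl_retry = float(courant[imax])
                break

            # record start-of-step state
            P_now = p_dia + beta / A_d * (np.sqrt(A) - sqrt_A_d)
            for key, idx in grid.site_nodes.items():
                rec[key]["P"].append(P_now[idx])
                rec[key]["Q"].append(Q[idx])
                rec[key]["A"].append(A[idx])

            # ---- MacCormack predictor (forward differences)
            F2 = Q * Q / A
            src = src_coef * Q / A
            dQ = np.zeros_like(Q)
            dF2 = np.zeros_like(Q)
            dP = np.zeros_like(Q)
            dQ[:-1] = Q[1:] - Q[:-1]
            dF2[:-1] = F2[1:] - F2[:-1]
            dP[:-1] = P_now[1:] - P_now[:-1]
            dQ[last] = 0.0
            dF2[last] = 0.0
            dP[last] = 0.0
            Ap = A - r * dQ
            Qp = Q - r * dF2 - dt * (A / rho) * dP / dx + dt * src
            np.maximum(Ap, 1e-6 * A_d, out=Ap)
            Pp = p_dia + beta / A_d * (np.sqrt(Ap) - sqrt_A_d)

            # ---- corrector (backward differences)
            F2p = Qp * Qp / Ap
            srcp = src_coef * Qp / Ap
            dQp = np.zeros_like(Q)
            dF2p = np.zeros_like(Q)
            dPp = np.zeros_like(Q)
            dQp[1:] = Qp[1:] - Qp[:-1]
            dF2p[1:] = F2p[1:] - F2p[:-1]
            dPp[1:] = Pp[1:] - Pp[:-1]
            dQp[first] = 0.0
            dF2p[first] = 0.0
            dPp[first] = 0.0
            A_new = 0.5 * (A + Ap - r * dQp)
            Q_new = 0.5 * (
                Q + Qp - r * dF2p - dt * (Ap / rho) * dPp / dx + dt * srcp
            )
            np.maximum(A_new, 1e-6 * A_d, out=A_new)

            if not np.all(np.isfinite(A_new)):
                raise SolverError("non-finite state (negative area or blow-up)")

            # ---- junction updates (characteristic feet from time-n state)
            for name, ports, sten in grid.junctions:
                feet = [
                    _foot_value(p, A, Q, beta, A_d, rho, dt) for p in ports
                ]
                try:
                    Ak, uk, defect = _solve_junction(
                        ports, sten, A, Q, rho, feet
                    )
                except SolverError as exc:
                    raise SolverError(f"at junction {name}: {exc}") from None
                qmax = max(float(np.max(np.abs(Q))), 1e-9)
                max_mass_defect = max(max_mass_defect, defect / qmax)
                for p, a_v, u_v in zip(ports, Ak, uk):
                    A_new[p.idx] = a_v
                    Q_new[p.idx] = a_v * u_v

            # ---- boundary updates
            for bc, port, wk in bstates:
                foot = _foot_value(port, A, Q, beta, A_d, rho, dt)
                if bc.variant == "inflow_Q":
                    Qp_t = bc.params["waveform"](t_np1)
                    a_v, u_v = _solve_inflow_Q(
                        port, Qp_t, foot, A[port.idx], beta, A_d, rho
                    )
                    A_new[port.idx] = a_v
                    Q_new[port.idx] = a_v * u_v
                elif bc.variant == "inflow_P":
                    P_t = bc.params["waveform"](t_np1)
                    root = math.sqrt(port.A_d) + (
                        P_t - port.p_dia
                    ) * port.A_d / port.beta
                    if root <= 0:
                        raise SolverError("inflow pressure below collapse")
                    a_v = root * root
                    c = math.sqrt(
                        port.beta * math.sqrt(a_v) / (2.0 * rho * port.A_d)
                    )
                    u_v = foot - port.sign * 4.0 * c
                    A_new[port.idx] = a_v
                    Q_new[port.idx] = a_v * u_v
                else:  # Windkessel outlets
                    Q_old_out = port.sign * Q[port.idx]
                    if bc.variant == "wk3":
                        wk.precompute(dt, Q_old_out)
                    else:
                        wk.precompute(dt, Q_old_out, t_n, t_np1)
                    a_v, u_v = _solve_wk_outlet(
                        port, wk, foot, A[port.idx], Q[port.idx] / A[port.idx],
                        rho,
                    )
                    A_new[port.idx] = a_v
                    Q_new[port.idx] = a_v * u_v
                    wk.commit(port.sign * a_v * u_v)

            A, Q = A_new, Q_new

        if cfl_retry is not None:
            # wave speed outgrew the cycle-start estimate: restore the
            # cycle-start state and redo the cycle with a smaller dt
            dt_shrink *= 0.95 / cfl_retry
            retries += 1
            if dt_shrink < 1e-3 or retries > 20:
                raise SolverError("CFL time step collapsed; check the network")
            A, Q = snap_A, snap_Q
            for (bc_, port_, wk), s in zip(bstates, snap_wk):
                if isinstance(wk, _WK3State):
                    wk.P_c = s
                elif isinstance(wk, _WKCorState):
                    wk.x = s.copy()
            continue

        # ---- periodicity check on the resampled cycle
        this_cycle = {}
        for key in grid.site_nodes:
            parr = np.interp(t_out, t_axis, np.asarray(rec[key]["P"]))
            qarr = np.interp(t_out, t_axis, np.asarray(rec[key]["Q"]))
            aarr = np.interp(t_out, t_axis, np.asarray(rec[key]["A"]))
            this_cycle[key] = (parr, qarr, aarr)
        if prev_cycle is not None:
            residual = 0.0
            for key in grid.site_nodes:
                p_new = this_cycle[key][0]
                p_old = prev_cycle[key][0]
                residual = max(
                    residual,
                    float(
                        np.linalg.norm(p_new - p_old)
                        / max(np.linalg.norm(p_old), 1e-30)
                    ),
                )
            if residual <= config.periodicity_tol:
                converged = True
                prev_cycle = this_cycle
                break
        prev_cycle = this_cycle
        cycle += 1

    sites = {}
    for key, (parr, qarr, aarr) in prev_cycle.items():
        sites[key] = {
            "P": PeriodicWaveform(t_out, parr, T),
            "Q": PeriodicWaveform(t_out, qarr, T),
            "A": PeriodicWaveform(t_out, aarr, T),
        }
    return SimulationResult(
        sites=sites,
        period=T,
        cycles_run=cycles,
        converged=converged,
        periodicity_residual=float(residual),
        max_junction_mass_defect=max_mass_defect,
        dt=dt_used,
    )
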