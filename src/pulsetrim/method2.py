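"""Method 2: per-site optimization of Windkessel parameters.

Each truncated site is treated independently: the flow waveform of the
baseline 1D solution at the cut face drives the WK3 ODE, and the parameters
are chosen to minimize the average relative error between the ODE pressure
and the baseline 1D pressure.  Following an identifiability analysis of the
three-parameter model, the optimization acts on theta = (R1/R2, C) with the
total resistance R1 + R2 held at (P_avg - P_out)/Q_avg; Method 1 supplies
the initial guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter

from .model import PeriodicWaveform, ValidationError, VascularNetwork
from .method1 import (
    SteadySolution,
    _cut_faces,
    characteristic_impedance,
    lumped_compliance,
    solve_steady,
    truncate_network,
)
from .solver import SimulationResult, SolverConfig, run_simulation

__all__ = ["WK3FitResult", "wk3_pressure_response", "fit_wk3",
           "reduce_with_method2"]


@dataclass
class WK3FitResult:
    R1: float
    R2: float
    C: float
    objective: float          # eps_P,avg at the optimum (fraction)
    initial_objective: float
    iterations: int
    initial_guess: str = ""
    warning: str | None = None

    @property
    def theta(self):
        return (self.R1 / self.R2, self.C)


def wk3_pressure_response(
    Q: PeriodicWaveform, R1, C, R2, P_out,
    drift_tol: float = 1e-8, max_cycles: int = 50,
) -> PeriodicWaveform:
    """Periodic pressure of a WK3 driven by the periodic flow Q(t).

    Integrates C dP_c/dt = Q - (P_c - P_out)/R2 with the Crank-Nicolson
    rule on Q's own grid, marching cycles until the start-of-cycle state
    drift is below ``drift_tol`` (relative), then returns P = P_c + R1*Q
    over one period.
    """
    q = Q.values
    n = len(q)
    dt = Q.dt
    kappa = dt / (2.0 * R2 * C)
    alpha = (1.0 - kappa) / (1.0 + kappa)
    q_next = np.roll(q, -1)
    beta = (dt / (2.0 * C) * (q + q_next) + 2.0 * kappa * P_out) / (1.0 + kappa)
    # homogeneous cycle response: y[k] = sum_j alpha^(k-j) beta[j]
    y = lfilter([1.0], [1.0, -alpha], beta)
    alpha_N = alpha ** n
    p = P_out + R2 * Q.mean() + R1 * 0.0  # start from the steady mean charge
    for _ in range(max_cycles):
        p_new = alpha_N * p + y[-1]
        if abs(p_new - p) <= drift_tol * max(abs(p_new), 1e-12):
            p = p_new
            break
        p = p_new
    powers = alpha ** np.arange(n)
    P_c = np.empty(n)
    P_c[0] = p
    P_c[1:] = powers[1:] * p + y[:-1]
    return PeriodicWaveform(Q.t.copy(), P_c + R1 * q, Q.period)


def _eps_avg_pressure(P_ref: np.ndarray, P_try: np.ndarray) -> float:
    return float(np.mean(np.abs((P_try - P_ref) / P_ref)))


def fit_wk3(
    Q_baseline: PeriodicWaveform,
    P_baseline: PeriodicWaveform,
    P_out: float,
    subset: str = "ratio_C",
    initial: dict | None = None,
    R_total: float | None = None,
    tol: float = 1e-10,
) -> WK3FitResult:
    """Fit WK3 parameters to baseline waveforms at a truncated site.

    subset "ratio_C" optimizes (R1/R2, C) with R1+R2 fixed; subset "C"
    optimizes the compliance only.  ``initial`` may carry "R1" and "C"
    guesses (e.g. Z_c and the lumped compliance from Method 1).
    """
    if len(P_baseline.values) != len(Q_baseline.values):
        P_baseline = P_baseline.resample(len(Q_baseline.values))
    P_ref = P_baseline.values
    if np.any(P_ref <= 0):
        raise ValidationError("baseline pressure crosses zero")
    Q_avg = Q_baseline.mean()
    P_avg = float(np.mean(P_ref))
    if R_total is None:
        R_total = (P_avg - P_out) / Q_avg
    if R_total <= 0:
        raise ValidationError("non-positive total resistance at the site")

    initial = dict(initial or {})
    R1_0 = initial.get("R1", 0.1 * R_total)
    R1_0 = min(max(R1_0, 1e-6 * R_total), 0.95 * R_total)
    C_0 = initial.get("C", 1.0 / R_total)  # ~1 s time constant fallback
    theta0 = np.array([R1_0 / (R_total - R1_0), C_0])

    def unpack(z):
        ratio, C = np.exp(z)
        R2 = R_total / (1.0 + ratio)
        R1 = R_total - R2
        return R1, C, R2

    def objective(z):
        R1, C, R2 = unpack(z)
        resp = wk3_pressure_response(Q_baseline, R1, C, R2, P_out)
        return _eps_avg_pressure(P_ref, resp.values)

    z0 = np.log(theta0)
    f0 = objective(z0)

    if subset == "C":
        obj = lambda zc: objective(np.array([z0[0], zc[0]]))
        res = minimize(
            obj, np.array([z0[1]]), method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-8, "maxiter": 400},
        )
        z_best = np.array([z0[0], res.x[0]])
    elif subset == "ratio_C":
        res = minimize(
            objective, z0, method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-8, "maxiter": 800},
        )
        z_best = res.x
    else:
        raise ValidationError(f"unknown parameter subset {subset!r}")

    f_best = objective(z_best)
    warning = None
    if f_best > f0:  # Nelder-Mead never worsens the best point, but be safe
        z_best, f_best, warning = z0, f0, "optimizer failed; initial kept"
    R1, C, R2 = unpack(z_best)
    return WK3FitResult(
        R1=R1, R2=R2, C=C, objective=f_best, initial_objective=f0,
        iterations=int(res.nit), initial_guess="method1" if initial else "default",
        warning=warning,
    )


def reduce_with_method2(
    net: VascularNetwork,
    baseline_result: SimulationResult,
    retained_ids,
    config: SolverConfig | None = None,
    ss: SteadySolution | None = None,
) -> VascularNetwork:
    """Build a reduced network whose cut faces carry fitted WK3 outlets.

    Coronary cut faces keep the Method 1 (algebraic) coronary Windkessel;
    the optimization applies to systemic WK3 faces.
    """
    if ss is None:
        ss = solve_steady(net)
    faces = _cut_faces(net, retained_ids)
    if not faces:
        return net.copy()

    needed = []
    for sid, end, node, bcs in faces:
        pos = 1.0 if end == "dist" else 0.0
        needed.append((sid, pos))
    missing = [
        s for s in needed
        if not any(k[0] == s[0] and abs(k[1] - s[1]) < 1e-9
                   for k in baseline_result.sites)
    ]
    if missing:
        if config is None:
            raise ValidationError(
                f"baseline result lacks waveforms at {missing} and no solver "
                "config was given to re-run it"
            )
        cfg = SolverConfig(
            dx_target=config.dx_target, cfl=config.cfl,
            max_cycles=config.max_cycles,
            periodicity_tol=config.periodicity_tol,
            output_sites=sorted(set(config.output_sites) | set(needed)),
            dt_override=config.dt_override,
        )
        baseline_result = run_simulation(net, cfg)

    reduced = truncate_network(net, ss, retained_ids)
    for (sid, end, node, bcs), site in zip(faces, needed):
        bc = reduced.boundary_at(node)
        if bc.variant != "wk3":
            continue  # coronary faces stay algebraic
        Q_wf = baseline_result.waveform(site[0], site[1], "Q")
        P_wf = baseline_result.waveform(site[0], site[1], "P")
        if end == "prox":
            Q_wf = PeriodicWaveform(Q_wf.t, -Q_wf.values, Q_wf.period)
        P_out = bc.params["P_out"]
        seg = net.segment(sid)
        guess = {
            "R1": characteristic_impedance(seg, ss, site[1]),
            "C": lumped_compliance(net, ss, site),
        }
        fit = fit_wk3(Q_wf, P_wf, P_out, subset="ratio_C", initial=guess)
        bc.params.update({"R1": fit.R1, "C": fit.C, "R2": fit.R2})
    return reduced
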