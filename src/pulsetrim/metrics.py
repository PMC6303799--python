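"""Waveform comparison metrics and clinical indices.

All epsilon metrics are dimensionless fractions (multiply by 100 for %).
Pressure errors are pointwise-relative; flow errors are normalized by the
baseline cycle maximum to avoid division near zero-flow instants.  Clinical
indices: pulse pressure, augmentation pressure (via the early-systolic
inflection point), iFR (wave-free distal/proximal pressure ratio) and FFR
(cycle-averaged ratio under hyperaemia).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .model import PeriodicWaveform, ValidationError

__all__ = [
    "MetricReport",
    "eps_avg",
    "eps_extrema",
    "eps_aug",
    "find_inflection",
    "ifr",
    "ffr",
    "input_impedance",
    "compare",
]


@dataclass
class MetricReport:
    eps_P_avg: float | None = None
    eps_Q_avg: float | None = None
    eps_P_sys: float | None = None
    eps_P_dia: float | None = None
    eps_PP: float | None = None
    eps_P_aug: float | None = None
    aug_defined: bool = True

    def as_percent(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, float):
                out[k] = 100.0 * v
        return out


def _align(baseline: PeriodicWaveform, reduced: PeriodicWaveform):
    """Resample the reduced waveform onto the baseline grid (baseline wins)."""
    b = baseline.values
    if len(reduced.values) == len(b) and np.allclose(
        reduced.t, baseline.t, rtol=0, atol=1e-12 * baseline.period
    ):
        r = reduced.values
    else:
        r = reduced(baseline.t / baseline.period * reduced.period)
    return b, np.asarray(r)


def eps_avg(baseline: PeriodicWaveform, reduced: PeriodicWaveform,
            kind: str = "pressure") -> float:
    """Average relative error over the cycle.

    pressure: mean |P_R - P_B| / |P_B| ; flow: mean |Q_R - Q_B| / max(Q_B).
    """
    b, r = _align(baseline, reduced)
    if kind == "pressure":
        if np.any(b == 0):
            raise ValidationError("baseline pressure crosses zero")
        return float(np.mean(np.abs((r - b) / b)))
    if kind == "flow":
        qmax = float(np.max(b))
        if qmax <= 0:
            raise ValidationError("baseline flow maximum must be positive")
        return float(np.mean(np.abs(r - b) / qmax))
    raise ValidationError(f"unknown kind {kind!r}")


def eps_extrema(baseline: PeriodicWaveform, reduced: PeriodicWaveform):
    """(eps_P_sys, eps_P_dia, eps_PP) from cycle extrema."""
    b, r = _align(baseline, reduced)
    sys_b, dia_b = float(np.max(b)), float(np.min(b))
    sys_r, dia_r = float(np.max(r)), float(np.min(r))
    pp_b = sys_b - dia_b
    if pp_b == 0:
        raise ValidationError("baseline pulse pressure is zero")
    return (
        abs(sys_b - sys_r) / sys_b,
        abs(dia_b - dia_r) / dia_b,
        abs(pp_b - (sys_r - dia_r)) / pp_b,
    )


def find_inflection(wave: PeriodicWaveform, window: int = 7, polyorder: int = 2):
    """Early-systolic inflection point (t_infl, P_infl), or None if absent.

    The waveform is smoothed with a Savitzky-Golay filter and the second
    derivative is scanned between the diastolic foot (cycle minimum before
    the systolic peak) and the absolute systolic peak.  A "-- to +" zero
    crossing marks the shoulder of an augmented wave and is preferred; a
    wave without one falls back to the first "+ to --" crossing (the
    deceleration shoulder past the maximum-slope point).
    """
    v = wave.values
    n = len(v)
    if n < window + 2:
        return None
    # roll the cycle so it starts at the global minimum (diastolic foot)
    i_min = int(np.argmin(v))
    vv = np.roll(v, -i_min)
    sm = savgol_filter(vv, window, polyorder, mode="wrap")
    d2 = savgol_filter(vv, window, polyorder, deriv=2, mode="wrap")
    i_peak = int(np.argmax(sm))
    if i_peak < 3:
        return None
    # skip the flat diastolic baseline where d2 is numerical noise
    rise = sm[:i_peak] - sm[0]
    above = np.nonzero(rise > 0.05 * (sm[i_peak] - sm[0]))[0]
    k0 = int(above[0]) if len(above) else 1
    seg = d2[k0:i_peak]
    sign = np.sign(seg)
    crossings_up = [
        k + k0 for k in range(len(seg) - 1)
        if sign[k] < 0 and sign[k + 1] > 0
    ]
    crossings_down = [
        k + k0 for k in range(len(seg) - 1)
        if sign[k] > 0 and sign[k + 1] < 0
    ]
    if crossings_up:
        i_infl = crossings_up[0]
    elif crossings_down:
        i_infl = crossings_down[0]
    else:
        return None
    i_orig = (i_infl + i_min) % n
    return float(wave.t[i_orig]), float(v[i_orig])


def eps_aug(baseline: PeriodicWaveform, reduced: PeriodicWaveform,
            window: int = 7) -> float | None:
    """Error in augmentation pressure (P_sys - P_infl), normalized by PP_B.

    Returns None (undefined) when either waveform lacks an inflection.
    """
    fb = find_inflection(baseline, window)
    fr = find_inflection(reduced, window)
    if fb is None or fr is None:
        return None
    sys_b = float(np.max(baseline.values))
    dia_b = float(np.min(baseline.values))
    pp_b = sys_b - dia_b
    if pp_b == 0:
        raise ValidationError("baseline pulse pressure is zero")
    sys_r = float(np.max(reduced.values))
    aug_b = sys_b - fb[1]
    aug_r = sys_r - fr[1]
    return abs(aug_b - aug_r) / pp_b


def ifr(P_proximal: PeriodicWaveform, P_distal: PeriodicWaveform,
        wave_free_fraction: float = 0.30) -> float:
    """Instantaneous wave-free ratio over the last fraction of the cycle."""
    b, d = _align(P_proximal, P_distal)
    n = len(b)
    k0 = int(np.floor(n * (1.0 - wave_free_fraction)))
    mp = float(np.mean(b[k0:]))
    if mp <= 0:
        raise ValidationError("non-positive proximal pressure in the window")
    return float(np.mean(d[k0:])) / mp


def ffr(P_proximal: PeriodicWaveform, P_distal: PeriodicWaveform) -> float:
    """Fractional flow reserve: cycle-mean distal / proximal pressure."""
    b, d = _align(P_proximal, P_distal)
    mp = float(np.mean(b))
    if mp <= 0:
        raise ValidationError("non-positive mean proximal pressure")
    return float(np.mean(d)) / mp


def input_impedance(P: PeriodicWaveform, Q: PeriodicWaveform,
                    n_harmonics: int | None = None):
    """Harmonic input impedance Z_k = P_k / Q_k at multiples of 1/T.

    Returns (frequencies Hz, |Z|, phase rad); the DC entry is
    mean(P)/mean(Q).  Harmonics with negligible flow content are omitted.
    """
    p, q = _align(P, Q)
    n = len(p)
    Pf = np.fft.rfft(p) / n
    Qf = np.fft.rfft(q) / n
    if n_harmonics is None:
        n_harmonics = len(Pf) - 1
    kmax = min(n_harmonics, len(Pf) - 1)
    q_ref = float(np.max(np.abs(Qf)))
    freqs, mag, phase = [], [], []
    if Qf[0].real != 0:
        freqs.append(0.0)
        mag.append(abs(Pf[0].real / Qf[0].real))
        phase.append(0.0)
    for k in range(1, kmax + 1):
        if abs(Qf[k]) < 1e-12 * max(q_ref, 1e-300):
            continue
        Z = Pf[k] / Qf[k]
        freqs.append(k / P.period)
        mag.append(abs(Z))
        phase.append(float(np.angle(Z)))
    return np.array(freqs), np.array(mag), np.array(phase)


def compare(baseline: PeriodicWaveform, reduced: PeriodicWaveform,
            kind: str = "pressure") -> MetricReport:
    """Full metric report between a baseline and a reduced waveform."""
    rep = MetricReport()
    if kind == "flow":
        rep.eps_Q_avg = eps_avg(baseline, reduced, "flow")
        return rep
    rep.eps_P_avg = eps_avg(baseline, reduced, "pressure")
    rep.eps_P_sys, rep.eps_P_dia, rep.eps_PP = eps_extrema(baseline, reduced)
    aug = eps_aug(baseline, reduced)
    if aug is None:
        rep.aug_defined = False
    else:
        rep.eps_P_aug = aug
    return rep
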