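"""Reading and writing network description files and waveform tables.

Network files are JSON documents with clinical units (cm, mm, mmHg):

.. code-block:: json

    {
      "blood": {"rho": 1.06, "mu": 0.035, "zeta": 9},
      "segments": [
        {"id": "ao", "name": "aorta", "length_cm": 10.0,
         "r_prox_mm": 10.0, "r_dist_mm": 10.0,
         "wall_law": "systemic", "p_dia_mmHg": 80.0}
      ],
      "connections": {"inlet": [["ao", "prox"]], "outlet": [["ao", "dist"]]},
      "stenoses": [],
      "boundaries": [
        {"node": "inlet", "variant": "inflow_Q",
         "params": {"waveform": {"t_s": [...], "values": [...],
                                 "period_s": 1.0, "unit": "ml/s"}}},
        {"node": "outlet", "variant": "wk3",
         "params": {"R1": 100.0, "C": 1e-4, "R2": 1500.0, "P_out_mmHg": 5.0}}
      ]
    }

Windkessel resistances and compliances are in CGS (dyn s/cm^5, cm^5/dyn);
pressures may use a ``_mmHg`` suffix.  ``"segments"`` may instead name a CSV
file (same columns) relative to the JSON file.  Waveforms are inline or
``{"csv": "path"}`` pointing to a two-column table ``t_s,<value>_<unit>``
with a ``# period_s=<T>`` comment line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ArterialSegment,
    BloodProperties,
    BoundaryCondition,
    PeriodicWaveform,
    StenosisDescriptor,
    ValidationError,
    VascularNetwork,
    WallLaw,
    wall_law_by_name,
)
from .units import MM, MMHG

__all__ = ["load_network", "save_network", "load_waveform", "save_waveform"]

_SEGMENT_COLUMNS = [
    "id", "name", "length_cm", "r_prox_mm", "r_dist_mm", "wall_law",
    "p_dia_mmHg",
]


def _wall_law_from_spec(spec) -> WallLaw:
    if isinstance(spec, str):
        return wall_law_by_name(spec)
    return WallLaw(
        k1=float(spec["k1"]), k2=float(spec["k2"]), k3=float(spec["k3"]),
        kind=spec.get("kind", "systemic"),
    )


def _segment_from_record(rec: dict) -> ArterialSegment:
    try:
        return ArterialSegment(
            id=str(rec["id"]),
            name=str(rec.get("name", "")),
            length=float(rec["length_cm"]),
            r_prox_dia=float(rec["r_prox_mm"]) * MM,
            r_dist_dia=float(rec["r_dist_mm"]) * MM,
            wall_law=_wall_law_from_spec(rec.get("wall_law", "systemic")),
            p_dia_ref=float(rec.get("p_dia_mmHg", 80.0)) * MMHG,
            beta_override=(
                float(rec["beta_override"])
                if rec.get("beta_override") is not None
                else None
            ),
            beta_scale=float(rec.get("beta_scale", 1.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"segment record missing field {exc}") from None


def _waveform_from_spec(spec, base: Path) -> PeriodicWaveform:
    if isinstance(spec, PeriodicWaveform):
        return spec
    if "csv" in spec:
        return load_waveform(base / spec["csv"])
    unit = spec.get("unit", "cgs")
    scale = {"ml/s": 1.0, "mmHg": MMHG, "cgs": 1.0}.get(unit)
    if scale is None:
        raise ValidationError(f"unknown waveform unit {unit!r}")
    return PeriodicWaveform(
        t=np.asarray(spec["t_s"], dtype=float),
        values=np.asarray(spec["values"], dtype=float) * scale,
        period=float(spec["period_s"]),
    )


def _boundary_from_record(rec: dict, base: Path) -> BoundaryCondition:
    params = dict(rec.get("params", {}))
    out = {}
    for key, val in params.items():
        if key.endswith("_mmHg"):
            out[key[:-5]] = float(val) * MMHG
        elif key in ("waveform", "lv_pressure"):
            out[key] = _waveform_from_spec(val, base)
        else:
            out[key] = float(val)
    variant = rec["variant"]
    if variant == "wk_cor":
        out.setdefault("gamma_im", 1.0)
        out.setdefault("alpha", 1.0)
    return BoundaryCondition(node=str(rec["node"]), variant=variant, params=out)


def load_network(path) -> VascularNetwork:
    """Load and validate a network description file (JSON schema above)."""
    path = Path(path)
    base = path.parent
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"cannot parse {path.name}: {exc}") from None

    seg_spec = doc.get("segments")
    if seg_spec is None:
        raise ValidationError("network file missing 'segments'")
    if isinstance(seg_spec, str):
        frame = pd.read_csv(base / seg_spec)
        records = frame.where(pd.notna(frame), None).to_dict("records")
    else:
        records = seg_spec
    segments = [_segment_from_record(r) for r in records]

    topo_raw = doc.get("connections")
    if topo_raw is None:
        raise ValidationError("network file missing 'connections'")
    topology = {
        str(node): [(str(sid), str(end)) for sid, end in ports]
        for node, ports in topo_raw.items()
    }

    stenoses = []
    for rec in doc.get("stenoses", []):
        stenoses.append(
            StenosisDescriptor(
                segment_id=str(rec["segment_id"]),
                x_start=float(rec["x_start_cm"]),
                length_s=float(rec["length_cm"]),
                A0=float(rec["A0_cm2"]),
                As=float(rec["As_cm2"]),
                K_visc=float(rec["K_visc"]),
                K_exp=float(rec["K_exp"]),
            )
        )

    boundaries = [_boundary_from_record(r, base) for r in doc.get("boundaries", [])]
    blood_rec = doc.get("blood", {})
    blood = BloodProperties(
        rho=float(blood_rec.get("rho", 1.06)),
        mu=float(blood_rec.get("mu", 0.035)),
        zeta=float(blood_rec.get("zeta", 9.0)),
    )
    return VascularNetwork(
        segments=segments, topology=topology, stenoses=stenoses,
        boundaries=boundaries, blood=blood,
    )


def _wall_law_to_spec(law: WallLaw):
    from .model import CORONARY_WALL_LAW, SYSTEMIC_WALL_LAW

    if law == SYSTEMIC_WALL_LAW:
        return "systemic"
    if law == CORONARY_WALL_LAW:
        return "coronary"
    return {"k1": law.k1, "k2": law.k2, "k3": law.k3, "kind": law.kind}


def _waveform_to_spec(wf: PeriodicWaveform):
    return {
        "t_s": wf.t.tolist(),
        "values": wf.values.tolist(),
        "period_s": wf.period,
        "unit": "cgs",
    }


def save_network(net: VascularNetwork, path) -> None:
    """Write a network back to the JSON schema (inverse of load_network)."""
    segments = []
    for s in net.segments:
        rec = {
            "id": s.id,
            "name": s.name,
            "length_cm": s.length,
            "r_prox_mm": s.r_prox_dia / MM,
            "r_dist_mm": s.r_dist_dia / MM,
            "wall_law": _wall_law_to_spec(s.wall_law),
            "p_dia_mmHg": s.p_dia_ref / MMHG,
        }
        if s.beta_override is not None:
            rec["beta_override"] = s.beta_override
        if s.beta_scale != 1.0:
            rec["beta_scale"] = s.beta_scale
        segments.append(rec)

    boundaries = []
    for b in net.boundaries:
        params = {}
        for key, val in b.params.items():
            if isinstance(val, PeriodicWaveform):
                params[key] = _waveform_to_spec(val)
            elif key in ("P_out",):
                params[key + "_mmHg"] = val / MMHG
            else:
                params[key] = val
        boundaries.append({"node": b.node, "variant": b.variant, "params": params})

    doc = {
        "blood": {"rho": net.blood.rho, "mu": net.blood.mu, "zeta": net.blood.zeta},
        "segments": segments,
        "connections": {n: [list(p) for p in ports] for n, ports in net.topology.items()},
        "stenoses": [
            {
                "segment_id": st.segment_id,
                "x_start_cm": st.x_start,
                "length_cm": st.length_s,
                "A0_cm2": st.A0,
                "As_cm2": st.As,
                "K_visc": st.K_visc,
                "K_exp": st.K_exp,
            }
            for st in net.stenoses
        ],
        "boundaries": boundaries,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_waveform(path) -> PeriodicWaveform:
    """Load a two-column delimited waveform table (t_s, value).

    The header names the value unit (e.g. ``Q_mls`` or ``P_mmHg``) and a
    comment line ``# period_s=<T>`` gives the period; without it the period
    is inferred from the grid spacing (T = t[-1] + dt).
    """
    path = Path(path)
    period = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "period_s=" in first:
        period = float(first.split("period_s=")[1])
    frame = pd.read_csv(path, comment="#")
    t = frame.iloc[:, 0].to_numpy(float)
    vals = frame.iloc[:, 1].to_numpy(float)
    col = frame.columns[1].lower()
    if "mmhg" in col:
        vals = vals * MMHG
    if period is None:
        if len(t) < 2:
            raise ValidationError("waveform table needs >= 2 samples or a period")
        period = t[-1] + (t[1] - t[0])
    # tolerate an explicit wrap sample at t = period
    if abs(t[-1] - period) <= 1e-9 * period:
        t, vals = t[:-1], vals[:-1]
    return PeriodicWaveform(t=t, values=vals, period=period)


def save_waveform(wf: PeriodicWaveform, path, kind: str = "Q") -> None:
    """Write a waveform as CSV; kind 'Q' emits ml/s, 'P' emits mmHg."""
    if kind == "P":
        header, vals = "t_s,P_mmHg", wf.values / MMHG
    else:
        header, vals = "t_s,Q_mls", wf.values
    with open(path, "w") as fh:
        fh.write(f"# period_s={wf.period}\n")
        fh.write(header + "\n")
        for t, v in zip(wf.t, vals):
            fh.write(f"{float(t)!r},{float(v)!r}\n")
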