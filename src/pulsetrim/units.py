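"""Unit conversion constants.

All internal computation is in CGS units: pressure in dyn/cm^2, flow in
cm^3/s, resistance in dyn*s/cm^5, compliance in cm^5/dyn.  File I/O and
reports use the clinical units mmHg, ml/s and mm.
"""

MMHG = 1333.22  # dyn/cm^2 per mmHg
MM = 0.1  # cm per mm


def mmhg_to_cgs(p):
    return p * MMHG


def cgs_to_mmhg(p):
    return p / MMHG
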