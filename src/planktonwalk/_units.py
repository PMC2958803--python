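"""Unit conversions.

Positions are carried in cm, velocities in µm/s throughout the package;
the single conversion factor lives here.
"""

#: micrometres per centimetre — the one place the cm/µm conversion appears
UM_PER_CM: float = 1.0e4


def um_s_to_cm_s(v_um_s):
    """Convert a velocity from µm/s to cm/s."""
    return v_um_s / UM_PER_CM


def cm_to_m(x_cm):
    return x_cm / 100.0
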