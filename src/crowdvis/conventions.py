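"""Angle conventions shared by scenarios, metrics and file I/O.

Internally headings are CCW radians from the world +x axis.  Trials are
laid out with the crowd walking along +y ("forward"), so the reported
heading — in files, metrics and anything user-facing — is in degrees,
measured from forward with positive values to the right (clockwise from
above).  This matches how perturbations are specified (+10 deg = a
rightward turn).
"""

from __future__ import annotations

import math

import numpy as np

from .optics import wrap_angle

#: internal heading of a walker facing "forward" (+y)
FORWARD = math.pi / 2.0


def heading_to_display_deg(heading):
    """Internal CCW-from-+x radians -> right-positive degrees from forward."""
    return np.degrees(wrap_angle(FORWARD - np.asarray(heading, dtype=float)))


def heading_from_display_deg(deg):
    """Right-positive degrees from forward -> internal CCW radians."""
    return wrap_angle(FORWARD - np.radians(np.asarray(deg, dtype=float)))
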