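"""Angle conventions shared by every module.

Polar angle is measured clockwise from the upper vertical meridian
(0 deg = up, 90 deg = right), the standard retinotopy convention, so the
rectangular duals are ``x = r*sin(theta)`` and ``y = r*cos(theta)``.
Angles are stored in [-180, 180); signed circular *distances* live in
(-180, 180] so that the 180-deg polar-angle bin is well defined.
"""

from __future__ import annotations

import numpy as np


def wrap_angle(theta):
    """Wrap angle(s) in degrees to the half-open interval [-180, 180)."""
    return (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_distance(delta):
    """Wrap signed circular distance(s) in degrees to (-180, 180]."""
    d = -((-np.asarray(delta, dtype=float) + 180.0) % 360.0 - 180.0)
    return d


def polar_to_cartesian(polar_angle, eccentricity):
    """(theta, r) in degrees -> (x, y) in degrees of visual angle."""
    t = np.deg2rad(np.asarray(polar_angle, dtype=float))
    r = np.asarray(eccentricity, dtype=float)
    return r * np.sin(t), r * np.cos(t)


def cartesian_to_polar(x, y):
    """(x, y) -> (theta in [-180, 180), r >= 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = wrap_angle(np.rad2deg(np.arctan2(x, y)))
    return theta, np.hypot(x, y)
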