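"""Angle conventions shared across the package.

Orientations are axial quantities (a fibril has no polarity), measured in
degrees counter-clockwise from the x axis and folded into the half-open
interval (-90, 90].  -90 is identified with +90.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fold_angle_deg", "axial_mean_deg"]


def fold_angle_deg(theta):
    """Fold angle(s) in degrees into (-90, 90] under the 180-deg identification."""
    t = np.asarray(theta, dtype=float)
    folded = (t + 90.0) % 180.0 - 90.0
    folded = np.where(folded == -90.0, 90.0, folded)
    if np.isscalar(theta) or folded.ndim == 0:
        return float(folded)
    return folded


def axial_mean_deg(angles_deg, weights=None):
    """Mean direction of an axial sample: circular mean on the doubled angle.

    For a unimodal axial distribution this estimates the modal orientation;
    it is well defined across the +/-90 wrap-around.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    if weights is None:
        c, s = np.cos(a).mean(), np.sin(a).mean()
    else:
        w = np.asarray(weights, dtype=float)
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError("weights must have positive total mass")
        c = float(np.dot(w, np.cos(a))) / wsum
        s = float(np.dot(w, np.sin(a))) / wsum
    if c == 0.0 and s == 0.0:
        raise ValueError("axial mean undefined: resultant length is zero")
    return fold_angle_deg(np.degrees(np.arctan2(s, c)) / 2.0)
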