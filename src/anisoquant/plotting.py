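"""Display helpers: polar frequency histograms and angle colour maps.

Stored data are never altered here; the 0.03 radial cap applied to polar
frequency histograms (for comparability across panels) is a display-only
clip of the drawn radii.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # file output only
import matplotlib.pyplot as plt
import numpy as np

from .orientation import OrientationField
from .stats import AngularHistogram, polar_frequency_histogram

__all__ = ["plot_polar_histogram", "plot_angle_map", "RADIAL_CAP"]

RADIAL_CAP = 0.03


def plot_polar_histogram(hist: AngularHistogram, radial_cap: float = RADIAL_CAP,
                         ax=None, color="tab:red"):
    """Polar plot of normalized frequencies over (-90, 90], mirrored to the
    antipodal half so the axial symmetry is visible; radii clipped at
    ``radial_cap`` for display."""
    norm = polar_frequency_histogram(hist)
    shown = np.clip(norm, 0.0, radial_cap) if radial_cap else norm
    theta = np.radians(hist.bin_centers)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    width = np.radians(hist.bin_width)
    for offset in (0.0, np.pi):  # antipodal mirror
        ax.bar(theta + offset, shown, width=width, bottom=0.0, color=color,
               alpha=0.8, linewidth=0)
    ax.set_rmax(radial_cap if radial_cap else max(shown.max(), 1e-6))
    ax.set_rticks([])
    return ax


def plot_angle_map(field: OrientationField, ax=None):
    """Colour-coded local orientation (hue = angle), masked by foreground."""
    if ax is None:
        _, ax = plt.subplots()
    shown = np.where(field.mask, field.angle, np.nan)
    im = ax.imshow(shown, cmap="hsv", vmin=-90, vmax=90, interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="orientation (deg)")
    ax.set_axis_off()
    return ax
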