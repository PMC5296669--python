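"""Orientation index and polar frequency histograms.

The orientation index (OI) is a nematic-type order parameter computed from
an angular frequency distribution N(theta) over (-90, 90] degrees::

    OI = sum_theta N(theta) * cos(2*(theta - theta_i)) / sum_theta N(theta)

where theta_i is the reference (alignment) angle of interest.  With theta_i
= 0 (the x axis), OI = 1 for perfect alignment along x, 0 for an isotropic
distribution and -1 for perfect alignment along y.  The equivalent form
2*<cos^2(theta - theta_i)> - 1 makes the range [-1, 1] explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import axial_mean_deg, fold_angle_deg

__all__ = [
    "AngularHistogram",
    "OrientationIndexResult",
    "orientation_index",
    "oi_from_angles",
    "polar_frequency_histogram",
    "modal_angle",
]


@dataclass(frozen=True)
class AngularHistogram:
    """Binned angular frequencies N(theta) over (-90, 90] degrees.

    Bins are equal width and cover exactly 180 degrees; ``bin_centers`` are
    the representative angles at which cosines are evaluated.  Centers may
    sit on any regular grid (e.g. integer degrees -89..90, where the bin at
    +90 wraps around the antipodal identification).
    """

    bin_centers: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.bin_centers, dtype=float)
        freq = np.asarray(self.frequencies, dtype=float)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("bin_centers must be a non-empty 1-D array")
        if freq.shape != centers.shape:
            raise ValueError("frequencies must match bin_centers in shape")
        if np.any(freq < 0) or not np.all(np.isfinite(freq)):
            raise ValueError("frequencies must be finite and non-negative")
        if centers.size > 1:
            widths = np.diff(centers)
            if not np.allclose(widths, widths[0], rtol=0, atol=1e-9):
                raise ValueError("bins must be equal width")
            span = centers.size * widths[0]
            if not np.isclose(span, 180.0, rtol=0, atol=1e-6):
                raise ValueError("bins must cover exactly 180 degrees")
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "frequencies", freq)

    @property
    def bin_width(self) -> float:
        if self.bin_centers.size == 1:
            return 180.0
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def total(self) -> float:
        return float(self.frequencies.sum())

    @classmethod
    def from_angles(cls, angles_deg, bin_width: float = 1.0, weights=None) -> "AngularHistogram":
        """Bin axial angles into centers at integer multiples of ``bin_width``.

        180 must be divisible by ``bin_width``.  Centers run from
        -90 + bin_width up to +90 so that 0 and 90 degrees are bin centers,
        matching the convention in which mass exactly on the x or y axis
        falls in a bin centered there.
        """
        if bin_width <= 0 or abs(round(180.0 / bin_width) * bin_width - 180.0) > 1e-9:
            raise ValueError("180 must be an integer multiple of bin_width")
        n_bins = int(round(180.0 / bin_width))
        a = fold_angle_deg(np.atleast_1d(np.asarray(angles_deg, dtype=float)))
        idx = np.round(a / bin_width).astype(int)
        # the -90 center is antipodal to +90; fold it up
        half = n_bins // 2
        idx = np.where(idx <= -half, idx + n_bins, idx)
        idx += half - 1  # center grid: (-90+w, ..., 90] -> 0..n_bins-1
        freq = np.bincount(idx, weights=weights, minlength=n_bins).astype(float)
        centers = -90.0 + bin_width * (1 + np.arange(n_bins))
        return cls(centers, freq)


@dataclass(frozen=True)
class OrientationIndexResult:
    """OI value, the reference angle it was evaluated against, and the
    total frequency mass that entered the average."""

    oi: float
    reference_angle: float
    n_effective: float

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.oi <= 1.0 + 1e-12:
            raise ValueError("OI outside [-1, 1]")


def orientation_index(hist: AngularHistogram, theta_i: float = 0.0) -> OrientationIndexResult:
    """Frequency-weighted mean of cos 2(theta - theta_i) over histogram bins."""
    total = hist.total
    if total <= 0:
        raise ValueError("orientation index undefined for all-zero frequencies")
    rel = np.radians(hist.bin_centers - theta_i)
    oi = float(np.dot(hist.frequencies, np.cos(2.0 * rel)) / total)
    return OrientationIndexResult(oi=float(np.clip(oi, -1.0, 1.0)),
                                  reference_angle=float(theta_i),
                                  n_effective=total)


def oi_from_angles(angles_deg, theta_i: float = 0.0) -> OrientationIndexResult:
    """Binless OI: mean of cos 2(theta - theta_i) over raw angles."""
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle list")
    oi = float(np.mean(np.cos(2.0 * np.radians(a - theta_i))))
    return OrientationIndexResult(oi=float(np.clip(oi, -1.0, 1.0)),
                                  reference_angle=float(theta_i),
                                  n_effective=float(a.size))


def polar_frequency_histogram(hist: AngularHistogram) -> np.ndarray:
    """Normalized frequencies N(theta)/sum N(theta); sums to 1.

    The 0.03 radial-axis cap used when drawing polar plots is a display
    convention only (see :mod:`anisoquant.plotting`); stored values are
    never clipped.
    """
    total = hist.total
    if total <= 0:
        raise ValueError("cannot normalize a histogram with zero total mass")
    return hist.frequencies / total


def modal_angle(hist_or_angles, weights=None) -> float:
    """Axial (doubled-angle) mean orientation of a sample or histogram."""
    if isinstance(hist_or_angles, AngularHistogram):
        return axial_mean_deg(hist_or_angles.bin_centers, hist_or_angles.frequencies)
    return axial_mean_deg(hist_or_angles, weights)
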