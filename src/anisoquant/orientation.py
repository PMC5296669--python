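"""Per-pixel local orientation of fibrous structures via the structure tensor.

The classical gradient structure tensor: image gradients are computed with
Gaussian-derivative filters at scale ``sigma_gradient``, their outer
product is averaged over a Gaussian window at scale ``sigma_window``, and
the orientation of the eigenvector with the SMALLEST eigenvalue — the
along-structure (ridge) direction, perpendicular to the dominant gradient —
is reported per pixel together with two confidence measures:

* coherence = (l_max - l_min)/(l_max + l_min) in [0, 1]: how strongly one
  orientation dominates locally;
* energy = l_max + l_min (the tensor trace): local gradient magnitude.

Angles follow the package convention: degrees counter-clockwise from the
x axis, folded into (-90, 90].  Array row 0 is the top of the image and the
y axis points up, so the row-derivative sign is flipped internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from ._angles import fold_angle_deg
from .stats import AngularHistogram

__all__ = ["OrientationField", "structure_tensor_orientation", "orientation_histogram"]

_WEIGHTINGS = ("none", "energy", "coherence_energy")


@dataclass(frozen=True)
class OrientationField:
    """Per-pixel orientation estimate for one image plane."""

    angle: np.ndarray      # degrees in (-90, 90]
    coherence: np.ndarray  # [0, 1]
    energy: np.ndarray     # >= 0
    mask: np.ndarray       # bool foreground

    def __post_init__(self):
        shapes = {self.angle.shape, self.coherence.shape, self.energy.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("angle, coherence, energy and mask must share one shape")
        if np.any(~np.isfinite(self.angle[self.mask])):
            raise ValueError("angle must be finite wherever mask is true")

    @property
    def masked_angles(self) -> np.ndarray:
        return self.angle[self.mask]


def structure_tensor_orientation(image: np.ndarray,
                                 sigma_gradient: float = 1.0,
                                 sigma_window: float = 2.0,
                                 energy_percentile: float = 50.0) -> OrientationField:
    """Estimate local orientation at every pixel of a 2-D image.

    ``energy_percentile`` sets the foreground mask: pixels whose tensor
    energy exceeds that percentile of the energy image are kept, which
    excludes flat background from downstream histograms.  Pixels within
    ceil(3*sigma_window) of the image border are always excluded from the
    mask: the averaging window hangs off the image there and the tensor is
    dominated by padding artefacts.  A constant image yields an all-false
    mask (and zero coherence), not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    min_side = 2 * int(np.ceil(3 * sigma_window)) + 1
    if min(img.shape) < min_side:
        raise ValueError(f"image sides must be >= {min_side} px for sigma_window={sigma_window}")

    # y axis points up: negate the row derivative
    ix = ndi.gaussian_filter(img, sigma_gradient, order=(0, 1), mode="nearest")
    iy = -ndi.gaussian_filter(img, sigma_gradient, order=(1, 0), mode="nearest")
    jxx = ndi.gaussian_filter(ix * ix, sigma_window, mode="nearest")
    jxy = ndi.gaussian_filter(ix * iy, sigma_window, mode="nearest")
    jyy = ndi.gaussian_filter(iy * iy, sigma_window, mode="nearest")

    energy = jxx + jyy
    delta = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(energy > 0, delta / np.where(energy > 0, energy, 1.0), 0.0)
    # dominant-gradient orientation, then +90 deg for the ridge direction;
    # an isotropic tensor (jxy = 0, jxx = jyy) gets atan2(0, 0) = 0 -> ridge
    # angle 90 folded; its coherence is 0 so it never dominates a histogram
    grad_angle = 0.5 * np.degrees(np.arctan2(2.0 * jxy, jxx - jyy))
    angle = fold_angle_deg(grad_angle + 90.0)
    # numerically degenerate tensors (flat regions): the angle there is
    # rounding noise; pin it to 0 with zero coherence, a scale-invariant rule
    degenerate = energy <= 1e-12 * max(float(energy.max()), 0.0)
    angle = np.where(degenerate, 0.0, angle)
    coherence = np.where(degenerate, 0.0, coherence)

    scale = max(float(np.abs(img).max()), 1.0)
    if float(energy.max()) <= 1e-12 * scale ** 2:
        mask = np.zeros(img.shape, dtype=bool)
        coherence = np.zeros_like(coherence)
    else:
        mask = energy > np.percentile(energy, energy_percentile)
        margin = int(np.ceil(3 * sigma_window))
        if margin > 0:
            mask[:margin, :] = False
            mask[-margin:, :] = False
            mask[:, :margin] = False
            mask[:, -margin:] = False
    return OrientationField(angle=angle, coherence=np.clip(coherence, 0.0, 1.0),
                            energy=energy, mask=mask)


def orientation_histogram(field: OrientationField, bin_width: float = 1.0,
                          weighting: str = "none") -> AngularHistogram:
    """Angular frequency histogram N(theta) of the masked pixels.

    ``weighting='none'`` counts pixels (the frequency export convention of
    OrientationJ-style analyses); ``'energy'`` and ``'coherence_energy'``
    weight each pixel by its confidence instead.
    """
    if weighting not in _WEIGHTINGS:
        raise ValueError(f"weighting must be one of {_WEIGHTINGS}")
    if not np.any(field.mask):
        raise ValueError("empty mask: no measurable oriented structure")
    angles = field.angle[field.mask]
    if weighting == "none":
        weights = None
    elif weighting == "energy":
        weights = field.energy[field.mask]
    else:
        weights = (field.coherence * field.energy)[field.mask]
    return AngularHistogram.from_angles(angles, bin_width=bin_width, weights=weights)
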