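"""Affine fibril reorientation under elastomer pre-deformation and release.

The culture chamber is an incompressible elastomer (PDMS) pre-deformed
uniaxially by a factor lambda = 1 + dL/L along the strain axis (y by
default); incompressibility forces the two transverse directions to scale
by lambda^{-1/2}.  Collagen loaded in the deformed chamber begins to
self-assemble; when the strain is released during the sol/gel biphasic
window, the viscoelastic matrix is carried back affinely: lambda^{-1} along
the strain axis, lambda^{+1/2} transverse.  A fibril axis v embedded in the
matrix maps to F v (renormalized), which in closed form gives, for release
of a pre-stretch along y,

    tan(theta_rs)    = lambda^{-3/2} tan(theta_0)     (xy azimuth from x)
    tan(phi_rs,yz)   = lambda^{+3/2} tan(phi_0,yz)    (yz polar from y)
    phi_rs,xz        = phi_0,xz                       (xz angle invariant)

so pre-stretch (lambda > 1) rotates fibrils toward the x axis and
pre-compression (lambda < 1) toward the y axis, exactly the perpendicular
alignment switch seen experimentally.

Fibrillogenesis timing enters through a logistic gelation curve f(t): only
the fraction of collagen already fibrillar at the moment of release can be
reoriented (and only if the network has not yet jammed); material that
assembles afterwards either templates onto the aligned fibrils or grows
isotropically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._angles import fold_angle_deg
from .stats import OrientationIndexResult, oi_from_angles
from .synthetic import FibrilEnsemble, generate_ensemble_3d

__all__ = [
    "DeformationGradient",
    "GelationKinetics",
    "StrainProtocol",
    "PlaneAngle",
    "pre_deformation_gradient",
    "release_deformation_gradient",
    "reorient",
    "plane_angle",
    "project_xy_angles",
    "predicted_oi_vs_strain",
    "gelation_fraction",
    "mixture_oi",
    "oi_vs_strain_duration",
]

_AXES = {"x": 0, "y": 1}
_PLANES = {"xy": (0, 1), "yz": (1, 2), "xz": (0, 2)}


@dataclass(frozen=True)
class DeformationGradient:
    """Diagonal, volume-preserving deformation (lambda_x, lambda_y, lambda_z)."""

    diag: tuple

    def __post_init__(self):
        d = tuple(float(v) for v in self.diag)
        if len(d) != 3 or any(v <= 0 for v in d):
            raise ValueError("diag must be three positive stretch factors")
        det = d[0] * d[1] * d[2]
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"deformation must be incompressible (det=1), got {det}")
        object.__setattr__(self, "diag", d)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.diag)


def pre_deformation_gradient(lam: float, axis: str = "y") -> DeformationGradient:
    """Uniaxial pre-deformation of the elastomer: lambda along ``axis``,
    lambda^{-1/2} in both transverse directions (incompressibility)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if axis not in _AXES:
        raise ValueError("axis must be 'x' or 'y'")
    d = [lam ** -0.5] * 3
    d[_AXES[axis]] = lam
    return DeformationGradient(tuple(d))


def release_deformation_gradient(lam: float, axis: str = "y") -> DeformationGradient:
    """Matrix deformation on strain release: lambda^{-1} along ``axis``,
    lambda^{+1/2} transverse (the inverse of the pre-deformation)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if axis not in _AXES:
        raise ValueError("axis must be 'x' or 'y'")
    d = [lam ** 0.5] * 3
    d[_AXES[axis]] = 1.0 / lam
    return DeformationGradient(tuple(d))


def reorient(ensemble: FibrilEnsemble, F: DeformationGradient) -> FibrilEnsemble:
    """Map every fibril axis v to F v / |F v| (affine embedding in the matrix)."""
    v = ensemble.directions * F.as_array()
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return FibrilEnsemble(v, ensemble.weights)


@dataclass(frozen=True)
class PlaneAngle:
    """In-plane angle of a fibril axis projection, degrees in (-90, 90].

    Measured from the x axis in the xy and xz planes and from the y axis in
    the yz plane (the plane's first-named axis).
    """

    plane: str
    angle: float

    def __post_init__(self):
        if self.plane not in _PLANES:
            raise ValueError("plane must be 'xy', 'yz' or 'xz'")
        if not -90.0 < self.angle <= 90.0:
            raise ValueError("angle must lie in (-90, 90]")


def plane_angle(v, plane: str) -> PlaneAngle:
    """Angle of the projection of ``v`` onto a coordinate plane."""
    if plane not in _PLANES:
        raise ValueError("plane must be 'xy', 'yz' or 'xz'")
    i, j = _PLANES[plane]
    v = np.asarray(v, dtype=float)
    a, b = v[i], v[j]
    if np.hypot(a, b) <= 1e-12:
        raise ValueError(f"projection onto {plane} is degenerate for this vector")
    return PlaneAngle(plane, fold_angle_deg(np.degrees(np.arctan2(b, a))))


def project_xy_angles(ensemble: FibrilEnsemble) -> np.ndarray:
    """xy azimuths (degrees from x, folded) of every non-degenerate axis."""
    v = ensemble.directions
    ok = np.hypot(v[:, 0], v[:, 1]) > 1e-12
    return fold_angle_deg(np.degrees(np.arctan2(v[ok, 1], v[ok, 0])))


def predicted_oi_vs_strain(delta_ratios: Iterable[float], n: int = 100_000,
                           seed: Optional[int] = None, axis: str = "y") -> pd.DataFrame:
    """Pure affine prediction of OI versus strain magnitude dL/L.

    For each dL/L an isotropic fibril ensemble (nucleation is random in the
    deformed chamber) is reoriented by the release deformation and the OI
    of the xy azimuths relative to the x axis is computed.  Each fibril
    contributes its projected azimuth with unit weight.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for dr in delta_ratios:
        lam = 1.0 + dr
        if lam <= 0:
            raise ValueError(f"dL/L = {dr} implies non-positive lambda")
        ens = generate_ensemble_3d(n, "isotropic", rng=rng)
        moved = reorient(ens, release_deformation_gradient(lam, axis))
        oi = oi_from_angles(project_xy_angles(moved), theta_i=0.0).oi
        rows.append({"delta_ratio": float(dr), "oi": oi, "n": n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GelationKinetics:
    """Sigmoidal fibrillogenesis kinetics and mixture-model parameters.

    ``t_lag``/``t_half``/``rate`` parametrize the logistic fibrillar
    fraction f(t) = 1/(1 + exp(-rate (t - t_half))), constrained so the lag
    phase really is a lag: f(t_lag) <= 0.05.  ``f_jam`` is the fibrillar
    fraction beyond which the network is too dense to reorient (release no
    longer aligns anything); ``template_efficiency`` is the probability
    that collagen assembling after release follows already-aligned fibrils
    rather than growing isotropically.
    """

    t_lag: float = 3.0
    t_half: float = 7.0
    rate: float = 0.75
    f_jam: float = 0.6
    template_efficiency: float = 0.5

    def __post_init__(self):
        if not 0 <= self.t_lag < self.t_half:
            raise ValueError("need 0 <= t_lag < t_half")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not 0 < self.f_jam <= 1:
            raise ValueError("f_jam must lie in (0, 1]")
        if not 0 <= self.template_efficiency <= 1:
            raise ValueError("template_efficiency must lie in [0, 1]")
        if gelation_fraction(self.t_lag, self, _validate=False) > 0.05:
            raise ValueError("kinetics violate the lag constraint f(t_lag) <= 0.05; "
                             "increase rate or the t_half - t_lag gap")


def gelation_fraction(t: float, k: GelationKinetics, _validate: bool = True) -> float:
    """Fibrillar fraction at time t (minutes): logistic with midpoint t_half."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return float(1.0 / (1.0 + np.exp(-k.rate * (t - k.t_half))))


@dataclass(frozen=True)
class StrainProtocol:
    """One pre-deformation experiment: magnitude, axis, strain duration."""

    delta_ratio: float
    strain_axis: str = "y"
    t_D: float = 5.0
    kinetics: GelationKinetics = field(default_factory=GelationKinetics)

    def __post_init__(self):
        if 1.0 + self.delta_ratio <= 0:
            raise ValueError("1 + dL/L must be positive")
        if self.strain_axis not in _AXES:
            raise ValueError("strain_axis must be 'x' or 'y'")
        if self.t_D < 0:
            raise ValueError("t_D must be >= 0")

    @property
    def lam(self) -> float:
        return 1.0 + self.delta_ratio


def mixture_oi(protocol: StrainProtocol, n: int = 100_000,
               seed: Optional[int] = None) -> OrientationIndexResult:
    """OI of the pooled fibril population for a full strain protocol.

    Three populations are pooled at their xy azimuths:

    * fraction f(t_D) assembled before release: affinely reoriented if
      f(t_D) <= f_jam, otherwise left isotropic (jammed network);
    * of the remaining 1 - f(t_D), a fraction ``template_efficiency``
      adopts the reoriented population's distribution (templated growth) —
      active only when a reoriented population exists;
    * the rest grows isotropically in the restored chamber.
    """
    rng = np.random.default_rng(seed)
    k = protocol.kinetics
    f = gelation_fraction(protocol.t_D, k)
    F = release_deformation_gradient(protocol.lam, protocol.strain_axis)

    n_pre = int(round(n * f))
    n_post = n - n_pre
    reoriented_exists = 0 < n_pre and f <= k.f_jam

    angles = []
    if n_pre > 0:
        pre = generate_ensemble_3d(n_pre, "isotropic", rng=rng)
        if reoriented_exists:
            pre = reorient(pre, F)
        angles.append(project_xy_angles(pre))
    if n_post > 0:
        n_templated = int(round(n_post * k.template_efficiency)) if reoriented_exists else 0
        if n_templated > 0:
            tmpl = reorient(generate_ensemble_3d(n_templated, "isotropic", rng=rng), F)
            angles.append(project_xy_angles(tmpl))
        n_iso = n_post - n_templated
        if n_iso > 0:
            angles.append(project_xy_angles(generate_ensemble_3d(n_iso, "isotropic", rng=rng)))
    return oi_from_angles(np.concatenate(angles), theta_i=0.0)


def oi_vs_strain_duration(durations: Iterable[float], delta_ratio: float = 0.5,
                          kinetics: Optional[GelationKinetics] = None,
                          n: int = 100_000, seed: Optional[int] = None) -> pd.DataFrame:
    """Sweep t_D at fixed dL/L: the alignment window of the mixture model."""
    kinetics = kinetics or GelationKinetics()
    durations = list(durations)
    rows = []
    ss = np.random.SeedSequence(seed)
    for t_d, child in zip(durations, ss.spawn(max(len(durations), 1))):
        proto = StrainProtocol(delta_ratio=delta_ratio, t_D=float(t_d), kinetics=kinetics)
        res = mixture_oi(proto, n=n, seed=int(child.generate_state(1)[0] % (2 ** 31)))
        rows.append({"t_D": float(t_d), "oi": res.oi, "n": n})
    return pd.DataFrame(rows)
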