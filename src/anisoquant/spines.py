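"""Rule-based dendritic-protrusion retention and classification.

Protrusions detected on a reconstructed dendrite surface are first screened
as spines — volume >= 0.020 um^3, maximal width <= 3 um, length between 0.2
and 2 um — and retained spines are then classified:

* mushroom: head diameter >= 0.35 um and head:neck ratio >= 1,
* stubby: non-mushroom with volume >= 0.040 um^3,
* thin: every other retained spine.

All threshold comparisons are inclusive.  Long protrusions failing the
length ceiling (> 2 um) are filopodia-like and are reported as rejected.

Note on voxel counts: the volume thresholds are quoted both as voxel counts
(5 and 10 voxels) and in um^3 (0.020 and 0.040).  At the spine voxel size
used (0.11 x 0.11 x 0.42 um => 0.005082 um^3/voxel) the two are
inconsistent (5 voxels = 0.0254 um^3); the um^3 values are authoritative
here, and :func:`voxels_to_volume` exposes the conversion so the
discrepancy stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Protrusion",
    "SpineClass",
    "classify_protrusion",
    "classify_table",
    "protrusion_density",
    "generate_protrusions",
    "voxels_to_volume",
    "SPINE_VOXEL_UM3",
]

# retention thresholds (um, um^3); inclusive comparisons throughout
MIN_SPINE_VOLUME = 0.020
STUBBY_MIN_VOLUME = 0.040
MAX_SPINE_WIDTH = 3.0
MIN_SPINE_LENGTH = 0.2
MAX_SPINE_LENGTH = 2.0
MUSHROOM_MIN_HEAD = 0.35
MUSHROOM_MIN_HEAD_NECK_RATIO = 1.0

SPINE_VOXEL_UM3 = 0.11 * 0.11 * 0.42  # 0.005082 um^3 per voxel


def voxels_to_volume(n_voxels: float, voxel_um3: float = SPINE_VOXEL_UM3) -> float:
    """Volume (um^3) implied by a voxel count at the spine voxel size."""
    if n_voxels < 0:
        raise ValueError("voxel count must be non-negative")
    return float(n_voxels) * voxel_um3


class SpineClass(Enum):
    REJECTED = "rejected"
    MUSHROOM = "mushroom"
    STUBBY = "stubby"
    THIN = "thin"


@dataclass(frozen=True)
class Protrusion:
    """Geometric descriptors of one dendritic protrusion (micrometres).

    ``neck_diameter`` may be 0 when no neck is measurable; the head:neck
    ratio is then undefined and the mushroom criterion fails.
    """

    length: float
    max_width: float
    volume: float
    head_diameter: float = 0.0
    neck_diameter: float = 0.0

    def __post_init__(self):
        for name in ("length", "max_width", "volume", "head_diameter", "neck_diameter"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


def classify_protrusion(p: Protrusion) -> SpineClass:
    """Assign exactly one class to a protrusion (total decision function)."""
    retained = (p.volume >= MIN_SPINE_VOLUME
                and p.max_width <= MAX_SPINE_WIDTH
                and MIN_SPINE_LENGTH <= p.length <= MAX_SPINE_LENGTH)
    if not retained:
        return SpineClass.REJECTED
    if (p.head_diameter >= MUSHROOM_MIN_HEAD
            and p.neck_diameter > 0
            and p.head_diameter / p.neck_diameter >= MUSHROOM_MIN_HEAD_NECK_RATIO):
        return SpineClass.MUSHROOM
    if p.volume >= STUBBY_MIN_VOLUME:
        return SpineClass.STUBBY
    return SpineClass.THIN


def classify_table(protrusions: Iterable[Protrusion]) -> pd.DataFrame:
    """Classify a batch; one row per protrusion with descriptors and class."""
    rows = []
    for p in protrusions:
        rows.append({"length_um": p.length, "max_width_um": p.max_width,
                     "volume_um3": p.volume, "head_um": p.head_diameter,
                     "neck_um": p.neck_diameter,
                     "class": classify_protrusion(p).value})
    return pd.DataFrame(rows, columns=["length_um", "max_width_um", "volume_um3",
                                       "head_um", "neck_um", "class"])


def protrusion_density(classes: Sequence[SpineClass], dendrite_length: float) -> float:
    """Retained protrusions per 10 um of dendrite."""
    if dendrite_length <= 0:
        raise ValueError("dendrite_length must be positive")
    n = sum(1 for c in classes if c is not SpineClass.REJECTED)
    return 10.0 * n / dendrite_length


def generate_protrusions(n: int, stage: str = "DIV21",
                         seed: Optional[int] = None) -> List[Protrusion]:
    """Sample synthetic protrusion descriptors for an immature (DIV10) or
    mature (DIV21) culture.

    DIV10 dendrites carry few, mostly filopodial protrusions: long and
    slender, usually failing the 2 um spine length ceiling.  DIV21
    dendrites carry predominantly mature spine geometries (mushroom and
    stubby dominate, with a thin minority).  Descriptors are drawn from
    stage-specific uniform/normal ranges chosen to land in the intended
    class region; boundary straddling is possible and intended.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if stage not in ("DIV10", "DIV21"):
        raise ValueError("stage must be 'DIV10' or 'DIV21'")
    rng = np.random.default_rng(seed)
    out: List[Protrusion] = []
    for _ in range(n):
        u = rng.random()
        if stage == "DIV10":
            if u < 0.7:  # filopodium: long, thin, no head
                out.append(Protrusion(
                    length=rng.uniform(2.2, 5.0),
                    max_width=rng.uniform(0.2, 0.6),
                    volume=rng.uniform(0.01, 0.05),
                    head_diameter=rng.uniform(0.05, 0.2),
                    neck_diameter=rng.uniform(0.05, 0.2)))
            else:  # sparse immature thin spine
                out.append(Protrusion(
                    length=rng.uniform(0.8, 1.9),
                    max_width=rng.uniform(0.2, 0.6),
                    volume=rng.uniform(0.021, 0.038),
                    head_diameter=rng.uniform(0.12, 0.3),
                    neck_diameter=rng.uniform(0.1, 0.25)))
        else:
            if u < 0.45:  # mushroom
                head = rng.uniform(0.4, 0.8)
                out.append(Protrusion(
                    length=rng.uniform(0.5, 1.6),
                    max_width=rng.uniform(0.5, 1.2),
                    volume=rng.uniform(0.06, 0.3),
                    head_diameter=head,
                    neck_diameter=head / rng.uniform(1.3, 2.5)))
            elif u < 0.75:  # stubby: bulky, no distinct head
                out.append(Protrusion(
                    length=rng.uniform(0.3, 0.9),
                    max_width=rng.uniform(0.4, 1.0),
                    volume=rng.uniform(0.045, 0.2),
                    head_diameter=rng.uniform(0.15, 0.3),
                    neck_diameter=rng.uniform(0.15, 0.3)))
            else:  # thin
                out.append(Protrusion(
                    length=rng.uniform(0.8, 1.9),
                    max_width=rng.uniform(0.2, 0.5),
                    volume=rng.uniform(0.021, 0.038),
                    head_diameter=rng.uniform(0.12, 0.3),
                    neck_diameter=rng.uniform(0.1, 0.25)))
    return out
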