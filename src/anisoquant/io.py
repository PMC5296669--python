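"""Reading and writing the package's file formats.

Images: single-channel TIFF or PNG, converted to float in [0, 1].
Orientation fields: multi-page float32 TIFF (angle, coherence, energy,
mask) so the full field round-trips losslessly enough for re-analysis.
Histograms: two-column CSV (bin_center_deg, frequency).  Results and run
manifests: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .orientation import OrientationField
from .stats import AngularHistogram

__all__ = [
    "read_image", "write_image", "write_field", "read_field",
    "write_histogram_csv", "read_histogram_csv", "write_json", "read_json",
]


def read_image(path) -> np.ndarray:
    """Load a grayscale image as float in [0, 1]; RGB inputs are averaged."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"expected a single 2-D plane, got shape {arr.shape}")
    peak = arr.max()
    if peak > 1.0:  # integer-typed input
        arr = arr / (255.0 if peak <= 255 else 65535.0)
    return np.clip(arr, 0.0, 1.0)


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        iio.imwrite(path, (np.clip(image, 0, 1) * 255).astype(np.uint8))


def write_field(path, field: OrientationField) -> None:
    """Store an orientation field as a 4-page float32 TIFF
    (angle, coherence, energy, mask)."""
    stack = np.stack([field.angle, field.coherence, field.energy,
                      field.mask.astype(float)]).astype(np.float32)
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def read_field(path) -> OrientationField:
    stack = tifffile.imread(Path(path)).astype(float)
    if stack.ndim != 3 or stack.shape[0] != 4:
        raise ValueError("orientation-field TIFF must have 4 pages")
    return OrientationField(angle=stack[0], coherence=stack[1],
                            energy=stack[2], mask=stack[3] > 0.5)


def write_histogram_csv(path, hist: AngularHistogram) -> None:
    pd.DataFrame({"bin_center_deg": hist.bin_centers,
                  "frequency": hist.frequencies}).to_csv(path, index=False)


def read_histogram_csv(path) -> AngularHistogram:
    df = pd.read_csv(path)
    if not {"bin_center_deg", "frequency"}.issubset(df.columns):
        raise ValueError("histogram CSV needs columns bin_center_deg, frequency")
    return AngularHistogram(df["bin_center_deg"].to_numpy(float),
                            df["frequency"].to_numpy(float))


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
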