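"""Core image containers and file round-trips.

Every stage of the pipeline consumes and produces :class:`IntensityImage`
(an 8-bit grayscale grid in a common reference frame, row-major, origin at
the top-left) and :class:`LabelMask` (an integer label grid aligned to an
image, with a name legend).  Intensities always live in [0, 255]; coordinates
are 0-based ``(row, col)`` and intervals are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


def as_uint8(data: np.ndarray) -> np.ndarray:
    """Round, clip to [0, 255] and cast to uint8."""
    return np.clip(np.rint(np.asarray(data, dtype=float)), 0, 255).astype(np.uint8)


@dataclass
class IntensityImage:
    """8-bit grayscale image plus provenance metadata.

    ``meta`` carries free-form provenance (gene id, probe id, plane tag
    C/L1/L2/M1/M2, series id) and is never interpreted by numerics.
    """

    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("IntensityImage requires a nonempty 2-D grid")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.data = arr

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "IntensityImage":
        return IntensityImage(self.data.copy(), dict(self.meta))


@dataclass
class LabelMask:
    """Integer region-label grid with a name -> label-value legend."""

    data: np.ndarray
    legend: dict

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("LabelMask requires a 2-D grid")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask for one named region."""
        return self.data == self.legend[name]

    def union(self, names) -> np.ndarray:
        out = np.zeros(self.data.shape, dtype=bool)
        for name in names:
            out |= self.mask(name)
        return out

    def area(self, name: str) -> int:
        return int(self.mask(name).sum())


def image_array(image) -> np.ndarray:
    """Accept an IntensityImage or a bare array; return the uint8 grid."""
    if isinstance(image, IntensityImage):
        return image.data
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        return as_uint8(arr)
    return arr


def read_image(path) -> IntensityImage:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    return IntensityImage(as_uint8(arr), {"source": str(path)})


def write_image(path, image) -> None:
    path = Path(path)
    arr = image_array(image)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def write_mask(path, mask: LabelMask) -> None:
    """Label grid as 16-bit TIFF plus a sidecar JSON legend."""
    path = Path(path)
    tifffile.imwrite(path, mask.data.astype(np.uint16))
    path.with_suffix(".json").write_text(json.dumps(mask.legend, indent=1))


def read_mask(path) -> LabelMask:
    path = Path(path)
    data = tifffile.imread(path).astype(np.int64)
    legend = json.loads(path.with_suffix(".json").read_text())
    return LabelMask(data, {k: int(v) for k, v in legend.items()})
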