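"""ROI intensity extraction and gray-level quantization.

Texture descriptors (co-occurrence matrices, local binary patterns) operate
on a small discrete alphabet of gray levels.  Intensities inside the ROI are
binned into G equal-width levels over the ROI's own intensity range; voxels
outside the ROI carry level 0 and never contribute.  First-order statistics
are computed on raw intensities, not on the quantized alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import InputError, VolumeROI


@dataclass
class QuantizedROI:
    """Gray-level map of a VolumeROI: level 0 outside the ROI, 1..G inside."""

    levels: np.ndarray
    G: int
    source: VolumeROI
    roi_min: float
    roi_max: float

    @property
    def mask(self) -> np.ndarray:
        return self.source.mask


def roi_intensities(roi: VolumeROI) -> np.ndarray:
    """In-ROI intensities in lexicographic voxel-index order."""
    return roi.volume[roi.mask]


def quantize(roi: VolumeROI, G: int = 32) -> QuantizedROI:
    """Equal-width binning of the ROI intensity range into G levels.

    level(v) = min(G, 1 + floor(G * (v - min) / (max - min))); a constant
    ROI maps every in-ROI voxel to level 1.
    """
    if G < 2:
        raise InputError(f"quantization level count G must be >= 2, got {G}")
    vals = roi_intensities(roi)
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(roi.volume.shape, dtype=np.int64)
    if hi == lo:
        levels[roi.mask] = 1
    else:
        scaled = np.floor(G * (roi.volume[roi.mask] - lo) / (hi - lo)).astype(np.int64)
        levels[roi.mask] = np.minimum(G, 1 + scaled)
    return QuantizedROI(levels=levels, G=G, source=roi, roi_min=lo, roi_max=hi)
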