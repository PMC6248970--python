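"""The feature registry: the ordered, named inventory of all 251 features.

Layout (fixed): 12 first-order statistics, 130 directional GLCM features,
100 LBP-TOP features, 9 semantic features.  Every feature vector produced
by the extraction pipeline follows this order, so tables written on one
machine align column-for-column with tables written on another.
"""

from __future__ import annotations

import numpy as np

from .data_io import VolumeROI
from .firstorder import FIRSTORDER_FEATURE_NAMES, FIRSTORDER_STAT_NAMES, firstorder_features
from .glcm import GLCM_FEATURE_NAMES, glcm_features
from .lbptop import LBP_FEATURE_NAMES, lbptop_features
from .preprocess import quantize, roi_intensities
from .semantic import SEMANTIC_FEATURE_NAMES, SemanticRecord, encode_semantic

FAMILIES = ("firstorder", "glcm", "lbptop", "semantic")


def registry_names(families: tuple[str, ...] = FAMILIES) -> list[str]:
    """Ordered feature names for the requested families (default: all 251)."""
    parts = {
        "firstorder": FIRSTORDER_FEATURE_NAMES,
        "glcm": GLCM_FEATURE_NAMES,
        "lbptop": LBP_FEATURE_NAMES,
        "semantic": SEMANTIC_FEATURE_NAMES,
    }
    out: list[str] = []
    for fam in families:
        out.extend(parts[fam])
    return out


def family_of(name: str) -> str:
    if name.startswith("stat_"):
        return "firstorder"
    if name.startswith("glcm_"):
        return "glcm"
    if name.startswith("lbp_"):
        return "lbptop"
    if name.startswith("sem_"):
        return "semantic"
    raise KeyError(f"feature {name!r} does not belong to any registry family")


def extract_features(roi: VolumeROI, record: SemanticRecord | None = None,
                     G: int = 32, firstorder_bins: int = 64) -> dict[str, float]:
    """Extract the full named feature vector for one patient.

    First-order features are computed on raw ROI intensities; GLCM and
    LBP-TOP on the G-level quantized ROI.  When a semantic record is given
    the vector has all 251 entries, otherwise the 242 image features.
    """
    out: dict[str, float] = {}
    fo = firstorder_features(roi_intensities(roi), n_bins=firstorder_bins)
    for s, v in zip(FIRSTORDER_STAT_NAMES, fo.values()):
        out[f"stat_{s}"] = float(v)
    q = quantize(roi, G=G)
    out.update(glcm_features(q))
    out.update(lbptop_features(q))
    if record is not None:
        out.update(encode_semantic(record))
    return out


def feature_vector(features: dict[str, float], names: list[str]) -> np.ndarray:
    return np.array([features[n] for n in names], dtype=float)
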