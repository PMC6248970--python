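"""LBP-TOP texture features: local binary patterns on three orthogonal planes.

Each in-ROI voxel is coded in the three orthogonal planes through it
(XY, XZ, YZ): the 8 neighbors on a circle of radius R are sampled by
bilinear interpolation on the quantized gray levels, each compared >= to
the center value, and the 8 comparison bits form a code in [0, 255].
Codes may be compressed by a mapping — u2 keeps the 58 "uniform" patterns
(at most two circular bit transitions) distinct and pools the rest, ri
collapses bitwise rotations, riu2 does both.  Per-plane histograms are
normalized to mass 1/3 each and concatenated, and 10 distribution
statistics summarise each concatenated histogram.  Ten (radius, mapping)
configurations x 10 statistics give the 100 features of this family.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .data_io import InputError
from .firstorder import local_maxima
from .preprocess import QuantizedROI

P_NEIGHBORS = 8

# neighbor >= center sets the bit; the comparison carries a small tolerance so
# bilinear round-off cannot flip an exact tie (e.g. four equal corners)
_TIE_EPS = 1e-9

MAPPING_BINS = {"basic": 256, "u2": 59, "ri": 36, "riu2": 10}

_MAPPING_SUFFIX = {"basic": "", "u2": "_u", "ri": "_ri", "riu2": "_riu2"}

LBP_STAT_NAMES = [
    "mean", "std", "skewness", "kurtosis", "range", "energy", "entropy",
    "maxVal", "argmax", "numMaxRel",
]

# Plane order is fixed: XY = (axis0, axis1), XZ = (axis0, axis2), YZ = (axis1, axis2).
PLANE_AXES = ((0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class LBPConfig:
    R: int
    mapping: str
    P: int = P_NEIGHBORS

    def __post_init__(self):
        if self.mapping not in MAPPING_BINS:
            raise InputError(f"unknown LBP mapping {self.mapping!r}")
        if self.P != 8:
            raise InputError("only P = 8 neighbors is supported")

    @property
    def bins_per_plane(self) -> int:
        return MAPPING_BINS[self.mapping]

    @property
    def name(self) -> str:
        return f"LBP{self.R}{_MAPPING_SUFFIX[self.mapping]}"


# The 10-configuration grid: radii 1..3 crossed with {basic, u2, ri}, plus riu2 at R=3.
LBP_CONFIGS: tuple[LBPConfig, ...] = tuple(
    [LBPConfig(R=r, mapping=m) for r in (1, 2, 3) for m in ("basic", "u2", "ri")]
    + [LBPConfig(R=3, mapping="riu2")]
)

LBP_FEATURE_NAMES = [
    f"lbp_{stat}_{cfg.name}" for cfg in LBP_CONFIGS for stat in LBP_STAT_NAMES
]


@dataclass
class LBPHistogram:
    config: LBPConfig
    h: np.ndarray
    sample_count: int

    @property
    def degenerate(self) -> bool:
        return self.sample_count == 0


# ---------------------------------------------------------------------------
# Code mappings
# ---------------------------------------------------------------------------

def _transitions(code: int, P: int = 8) -> int:
    t = 0
    for k in range(P):
        b0 = (code >> k) & 1
        b1 = (code >> ((k + 1) % P)) & 1
        t += b0 != b1
    return t


def _rotation_min(code: int, P: int = 8) -> int:
    full = (1 << P) - 1
    return min(((code >> r) | (code << (P - r))) & full for r in range(P))


@lru_cache(maxsize=None)
def mapping_table(P: int = 8, mapping: str = "basic") -> np.ndarray:
    """Lookup table sending each raw 8-bit code to its histogram bin index."""
    if P != 8:
        raise InputError("only P = 8 is supported")
    codes = np.arange(256)
    if mapping == "basic":
        return codes.copy()
    if mapping == "u2":
        uniform = [c for c in range(256) if _transitions(c) <= 2]
        table = np.full(256, len(uniform), dtype=np.int64)  # catch-all bin
        for idx, c in enumerate(uniform):
            table[c] = idx
        return table
    if mapping == "ri":
        mins = np.array([_rotation_min(c) for c in range(256)])
        distinct = np.unique(mins)
        rank = {v: i for i, v in enumerate(distinct)}
        return np.array([rank[m] for m in mins], dtype=np.int64)
    if mapping == "riu2":
        table = np.empty(256, dtype=np.int64)
        for c in range(256):
            table[c] = bin(c).count("1") if _transitions(c) <= 2 else P_NEIGHBORS + 1
        return table
    raise InputError(f"unknown LBP mapping {mapping!r}")


# ---------------------------------------------------------------------------
# Code computation
# ---------------------------------------------------------------------------

def _neighbor_offsets(R: int, P: int = 8) -> list[tuple[float, float]]:
    """(da, db) displacement of neighbor k at angle 2*pi*k/P, axis-snap at 1e-9."""
    out = []
    for k in range(P):
        theta = 2.0 * np.pi * k / P
        a, b = R * np.cos(theta), R * np.sin(theta)
        a = round(a) if abs(a - round(a)) < 1e-9 else a
        b = round(b) if abs(b - round(b)) < 1e-9 else b
        out.append((a, b))
    return out


def lbp_code(plane: np.ndarray, center: tuple[int, int], P: int = 8, R: int = 1) -> int:
    """LBP code of one pixel of a 2D array; bit k set iff neighbor_k >= center."""
    plane = np.asarray(plane, dtype=float)
    r0, c0 = center
    n0, n1 = plane.shape
    if not (R <= r0 <= n0 - 1 - R and R <= c0 <= n1 - 1 - R):
        raise InputError(f"sampling circle of radius {R} at {center} exits plane bounds {plane.shape}")
    cval = plane[r0, c0]
    code = 0
    for k, (da, db) in enumerate(_neighbor_offsets(R, P)):
        a, b = r0 + da, c0 + db
        fa, fb = int(np.floor(a)), int(np.floor(b))
        ta, tb = a - fa, b - fb
        fa1, fb1 = min(fa + 1, n0 - 1), min(fb + 1, n1 - 1)
        val = ((1 - ta) * (1 - tb) * plane[fa, fb] + ta * (1 - tb) * plane[fa1, fb]
               + (1 - ta) * tb * plane[fa, fb1] + ta * tb * plane[fa1, fb1])
        if val >= cval - _TIE_EPS:
            code |= 1 << k
    return code


def _volume_plane_codes(levels: np.ndarray, axes: tuple[int, int], R: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of every voxel in the given plane orientation, plus circle-fit validity.

    Wrap-around values introduced by np.roll only touch voxels outside the
    validity margin, which are masked out.
    """
    lv = np.asarray(levels, dtype=float)
    code = np.zeros(lv.shape, dtype=np.int64)
    for k, (da, db) in enumerate(_neighbor_offsets(R)):
        fa, fb = int(np.floor(da)), int(np.floor(db))
        ta, tb = da - fa, db - fb

        def shifted(ia: int, ib: int) -> np.ndarray:
            sh = [0, 0, 0]
            sh[axes[0]], sh[axes[1]] = -ia, -ib
            return np.roll(lv, shift=tuple(sh), axis=(0, 1, 2))

        if ta == 0 and tb == 0:
            nb = shifted(fa, fb)
        else:
            nb = ((1 - ta) * (1 - tb) * shifted(fa, fb)
                  + ta * (1 - tb) * shifted(fa + 1, fb)
                  + (1 - ta) * tb * shifted(fa, fb + 1)
                  + ta * tb * shifted(fa + 1, fb + 1))
        code |= (nb >= lv - _TIE_EPS).astype(np.int64) << k

    valid = np.ones(lv.shape, dtype=bool)
    for ax in axes:
        n = lv.shape[ax]
        idx = np.arange(n)
        ok = (idx >= R) & (idx <= n - 1 - R)
        sh = [1, 1, 1]
        sh[ax] = n
        valid &= ok.reshape(sh)
    return code, valid


def lbp_top_histogram(q: QuantizedROI, config: LBPConfig) -> LBPHistogram:
    """Concatenated three-plane LBP histogram of the ROI.

    Each plane's histogram is normalized to mass 1/3 over the voxels whose
    sampling circle fits inside the volume bounds in that plane; the full
    histogram sums to 1 when all three planes have samples.
    """
    table = mapping_table(config.P, config.mapping)
    nbins = config.bins_per_plane
    parts = []
    total = 0
    for axes in PLANE_AXES:
        codes, valid = _volume_plane_codes(q.levels, axes, config.R)
        sel = valid & q.mask
        n_sel = int(sel.sum())
        total += n_sel
        counts = np.bincount(table[codes[sel]], minlength=nbins).astype(float)
        parts.append(counts / (3.0 * n_sel) if n_sel > 0 else counts)
    return LBPHistogram(config=config, h=np.concatenate(parts), sample_count=total)


# ---------------------------------------------------------------------------
# Histogram summary statistics
# ---------------------------------------------------------------------------

def lbp_summary(hist: LBPHistogram) -> dict[str, float]:
    """Ten distribution statistics of a concatenated LBP histogram.

    The histogram is treated as a distribution over its bin indices; "range"
    is the number of occupied bins (pattern diversity).  A zero histogram
    (no codable voxel) returns all zeros.
    """
    h = hist.h
    if hist.degenerate or h.sum() == 0:
        return {s: 0.0 for s in LBP_STAT_NAMES}
    w = h / h.sum()
    i = np.arange(h.size, dtype=float)
    mean = float(i @ w)
    m2 = float(((i - mean) ** 2) @ w)
    std = float(np.sqrt(m2))
    if m2 == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(((i - mean) ** 3) @ w) / m2 ** 1.5
        kurt = float(((i - mean) ** 4) @ w) / m2 ** 2
    nz = h[h > 0]
    i_star = int(np.argmax(h))
    return {
        "mean": mean,
        "std": std,
        "skewness": skew,
        "kurtosis": kurt,
        "range": float((h > 0).sum()),
        "energy": float((h ** 2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "maxVal": float(h[i_star]),
        "argmax": float(i_star),
        "numMaxRel": float(local_maxima(h).size),
    }


def lbptop_features(q: QuantizedROI) -> dict[str, float]:
    """All 100 LBP-TOP features, in registry order."""
    out: dict[str, float] = {}
    for cfg in LBP_CONFIGS:
        stats = lbp_summary(lbp_top_histogram(q, cfg))
        for s in LBP_STAT_NAMES:
            out[f"lbp_{s}_{cfg.name}"] = stats[s]
    return out
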