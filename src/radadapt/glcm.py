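"""3D gray-level co-occurrence matrix (GLCM) texture features.

A GLCM at displacement d counts ordered pairs of quantized gray levels
(v(x), v(x+d)) over voxels x with both x and x+d inside the ROI, normalized
to a joint probability matrix.  Ten scalar statistics are taken per matrix.
Only one displacement per +/- equivalence class is kept: under the
both-in-ROI pairing rule GLCM(-d) is exactly the transpose of GLCM(d), and
every statistic in the set is transpose-invariant, so signed duplicates
would be perfectly correlated features.  With 13 canonical unit
displacements this family contributes 13 x 10 = 130 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import QuantizedROI

# One representative per +/- pair of the 26 unit-cube offsets, fixed order.
# (0,-1,0) and (-1,1,-1) are the canonical picks for their classes.
DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, -1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (-1, 1, -1), (1, -1, -1),
)

GLCM_STAT_NAMES = [
    "energy", "entropy", "inertia", "absolute", "idm", "correlation",
    "sumAverage", "variance", "clusterShade", "clusterProminence",
]


def direction_name(d: tuple[int, int, int]) -> str:
    return ",".join(str(c) for c in d)


GLCM_FEATURE_NAMES = [
    f"glcm_{stat}_{direction_name(d)}" for d in DIRECTIONS for stat in GLCM_STAT_NAMES
]


@dataclass
class GLCMatrix:
    direction: tuple[int, int, int]
    P: np.ndarray
    pair_count: int

    @property
    def degenerate(self) -> bool:
        return self.pair_count == 0


def glcm(q: QuantizedROI, d: tuple[int, int, int]) -> GLCMatrix:
    """Co-occurrence matrix for displacement d (unsymmetrized).

    A voxel pair contributes iff both endpoints lie inside the ROI.  An ROI
    too thin along d yields a zero matrix, flagged via pair_count == 0.
    """
    dx, dy, dz = d
    if (dx, dy, dz) == (0, 0, 0) or not all(c in (-1, 0, 1) for c in d):
        raise ValueError(f"displacement must be a nonzero vector over {{-1,0,1}}, got {d}")
    lv, mask = q.levels, q.mask
    nx, ny, nz = lv.shape

    def span(n, c):
        # source slice paired with source+c must stay in bounds
        return slice(max(0, -c), min(n, n - c))

    sx, sy, sz = span(nx, dx), span(ny, dy), span(nz, dz)
    src_lv = lv[sx, sy, sz]
    src_m = mask[sx, sy, sz]
    tx = slice(sx.start + dx, sx.stop + dx)
    ty = slice(sy.start + dy, sy.stop + dy)
    tz = slice(sz.start + dz, sz.stop + dz)
    dst_lv = lv[tx, ty, tz]
    dst_m = mask[tx, ty, tz]

    both = src_m & dst_m
    i = src_lv[both] - 1
    j = dst_lv[both] - 1
    G = q.G
    counts = np.zeros((G, G), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    n_pairs = int(counts.sum())
    P = counts / n_pairs if n_pairs > 0 else counts.astype(float)
    return GLCMatrix(direction=tuple(d), P=P, pair_count=n_pairs)


def glcm_stats(M: GLCMatrix) -> dict[str, float]:
    """Ten scalar statistics of a co-occurrence matrix.

    Gray levels index from 1, so the marginal means live on 1..G.  A zero
    (degenerate) matrix returns all zeros.
    """
    if M.degenerate:
        return {s: 0.0 for s in GLCM_STAT_NAMES}
    P = M.P
    G = P.shape[0]
    i = np.arange(1, G + 1, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sig_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sig_y = float(np.sqrt(((i - mu_y) ** 2) @ py))
    ii = i[:, None]
    jj = i[None, :]
    diff = ii - jj
    ssum = ii + jj - mu_x - mu_y

    nz = P[P > 0]
    stats = {
        "energy": float((P ** 2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "inertia": float((diff ** 2 * P).sum()),
        "absolute": float((np.abs(diff) * P).sum()),
        "idm": float((P / (1.0 + diff ** 2)).sum()),
        "sumAverage": float(((ii + jj) * P).sum()),
        # symmetrized so the statistic is invariant under d -> -d (transpose)
        "variance": float(0.5 * (((ii - mu_x) ** 2 * P).sum()
                                 + ((jj - mu_y) ** 2 * P).sum())),
        "clusterShade": float((ssum ** 3 * P).sum()),
        "clusterProminence": float((ssum ** 4 * P).sum()),
    }
    if sig_x == 0.0 or sig_y == 0.0:
        stats["correlation"] = 0.0
    else:
        stats["correlation"] = float(((ii - mu_x) * (jj - mu_y) * P).sum() / (sig_x * sig_y))
    return stats


def glcm_features(q: QuantizedROI) -> dict[str, float]:
    """All 130 directional GLCM features, in registry order."""
    out: dict[str, float] = {}
    for d in DIRECTIONS:
        stats = glcm_stats(glcm(q, d))
        dn = direction_name(d)
        for s in GLCM_STAT_NAMES:
            out[f"glcm_{s}_{dn}"] = stats[s]
    return out
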