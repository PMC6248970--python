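"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from its definition by direct enumeration,
sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates


def glcm_brute(levels: np.ndarray, mask: np.ndarray, d: tuple[int, int, int], G: int):
    """Exhaustive ordered-pair co-occurrence counting (both endpoints in ROI)."""
    nx, ny, nz = levels.shape
    dx, dy, dz = d
    counts = np.zeros((G, G))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                u, v, w = x + dx, y + dy, z + dz
                if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                    counts[levels[x, y, z] - 1, levels[u, v, w] - 1] += 1
    total = counts.sum()
    return (counts / total if total > 0 else counts), int(total)


def _transitions_str(code: int, P: int = 8) -> int:
    bits = format(code, f"0{P}b")
    return sum(bits[i] != bits[(i + 1) % P] for i in range(P))


def _rotmin_str(code: int, P: int = 8) -> int:
    bits = format(code, f"0{P}b")
    return min(int(bits[r:] + bits[:r], 2) for r in range(P))


def mapping_brute(mapping: str, P: int = 8) -> np.ndarray:
    """Mapping tables recomputed via string bit manipulation."""
    if mapping == "basic":
        return np.arange(256)
    if mapping == "u2":
        uniform = [c for c in range(256) if _transitions_str(c) <= 2]
        table = np.full(256, len(uniform))
        for i, c in enumerate(uniform):
            table[c] = i
        return table
    if mapping == "ri":
        mins = [_rotmin_str(c) for c in range(256)]
        ranks = {v: i for i, v in enumerate(sorted(set(mins)))}
        return np.array([ranks[m] for m in mins])
    if mapping == "riu2":
        return np.array([
            format(c, "08b").count("1") if _transitions_str(c) <= 2 else 9
            for c in range(256)
        ])
    raise ValueError(mapping)


def lbp_plane_code_brute(plane: np.ndarray, r0: int, c0: int, R: int) -> int:
    """Per-angle neighbor sampling through scipy's bilinear interpolation.

    Angles that land on the axes are snapped to exact integer offsets, as
    the exact-arithmetic definition implies.
    """
    center = plane[r0, c0]
    code = 0
    for k in range(8):
        theta = 2 * np.pi * k / 8
        da, db = R * np.cos(theta), R * np.sin(theta)
        if abs(da - round(da)) < 1e-9:
            da = round(da)
        if abs(db - round(db)) < 1e-9:
            db = round(db)
        val = map_coordinates(plane.astype(float), [[r0 + da], [c0 + db]], order=1)[0]
        if val >= center - 1e-9:  # ties set the bit, robust to round-off
            code |= 1 << k
    return code


def lbp_top_hist_brute(levels: np.ndarray, mask: np.ndarray, R: int, mapping: str):
    """Per-voxel, per-plane LBP histogram by direct enumeration."""
    table = mapping_brute(mapping)
    nbins = int(table.max()) + 1
    planes = ((0, 1), (0, 2), (1, 2))
    parts = []
    total = 0
    for a0, a1 in planes:
        counts = np.zeros(nbins)
        nsel = 0
        it = np.ndindex(levels.shape)
        for idx in it:
            if not mask[idx]:
                continue
            if not (R <= idx[a0] <= levels.shape[a0] - 1 - R):
                continue
            if not (R <= idx[a1] <= levels.shape[a1] - 1 - R):
                continue
            sl = [idx[0], idx[1], idx[2]]
            sl[a0], sl[a1] = slice(None), slice(None)
            plane = levels[tuple(sl)]
            # plane axes keep volume-axis order since a0 < a1
            code = lbp_plane_code_brute(plane, idx[a0], idx[a1], R)
            counts[table[code]] += 1
            nsel += 1
        parts.append(counts / (3 * nsel) if nsel else counts)
        total += nsel
    return np.concatenate(parts), total


def b632plus_brute(err_bar: float, eps0: float, gamma: float) -> float:
    """Independent rendering of the .632+ combination rule."""
    eps0_prime = min(eps0, gamma)
    if gamma > err_bar and eps0 > err_bar:
        r = (eps0 - err_bar) / (gamma - err_bar)
        r = 0.0 if r < 0 else (1.0 if r > 1 else r)
    else:
        r = 0.0
    weight = 0.632 / (1.0 - 0.368 * r)
    return (1.0 - weight) * err_bar + weight * eps0_prime
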