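"""First-order (intensity histogram) statistical features.

Twelve scalars summarise the distribution of raw ROI intensities: the first
four moments of the values themselves, plus eight descriptors of the
normalized intensity histogram — its width, energy, entropy, the absolute
maximum (height and position), the energy in a +/-2-bin window around that
maximum, and the number and energy of relative maxima.

Moment conventions: population-normalized standard deviation, skewness
m3/m2^1.5, non-excess kurtosis m4/m2^2 (Gaussian -> 3).  A constant input is
degenerate: skewness and kurtosis are reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import InputError

FIRSTORDER_STAT_NAMES = [
    "mean", "std", "skewness", "kurtosis", "width", "energy", "entropy",
    "maxVal", "maxPos", "energyAroundMax", "numMaxRel", "energyRelMax",
]

FIRSTORDER_FEATURE_NAMES = [f"stat_{s}" for s in FIRSTORDER_STAT_NAMES]


@dataclass
class FirstOrderResult:
    mean: float
    std: float
    skewness: float
    kurtosis: float
    width: float
    energy: float
    entropy: float
    maxVal: float
    maxPos: float
    energyAroundMax: float
    numMaxRel: float
    energyRelMax: float
    degenerate: bool = False

    def values(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in FIRSTORDER_STAT_NAMES], dtype=float)


def firstorder_histogram(intensities, n_bins: int = 64):
    """Normalized equal-width histogram over [min, max].

    Returns ``(centers, probabilities)`` with the probabilities summing to 1.
    A constant input collapses to a single bin with probability 1.
    """
    vals = np.asarray(intensities, dtype=float).ravel()
    if vals.size == 0:
        raise InputError("cannot build a histogram from an empty intensity list")
    if n_bins < 1:
        raise InputError(f"n_bins must be positive, got {n_bins}")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return np.array([lo]), np.array([1.0])
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / counts.sum()


def local_maxima(p: np.ndarray) -> np.ndarray:
    """Indices of relative maxima of a sequence, plateau-aware.

    A maximal run of equal values counts once (at its left edge) when it is
    strictly higher than both flanking values; a boundary run compares only
    its inner neighbor.  For pairwise-distinct values this is the usual
    strict local-maximum rule.  A length-1 sequence has one maximum.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.array([0])
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and p[j + 1] == p[i]:
            j += 1
        left_ok = i == 0 or p[i - 1] < p[i]
        right_ok = j == n - 1 or p[j + 1] < p[i]
        if left_ok and right_ok:
            out.append(i)
        i = j + 1
    return np.array(out, dtype=int)


def firstorder_features(intensities, n_bins: int = 64) -> FirstOrderResult:
    """Compute the 12 first-order features from raw intensities."""
    vals = np.asarray(intensities, dtype=float).ravel()
    if vals.size < 2:
        raise InputError(f"need at least 2 intensity values, got {vals.size}")

    mean = float(vals.mean())
    m2 = float(((vals - mean) ** 2).mean())
    std = float(np.sqrt(m2))
    degenerate = m2 == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        m3 = float(((vals - mean) ** 3).mean())
        m4 = float(((vals - mean) ** 4).mean())
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2

    centers, p = firstorder_histogram(vals, n_bins)
    occupied = np.where(p > 0)[0]
    width = float(centers[occupied[-1]] - centers[occupied[0]])
    energy = float((p ** 2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    i_star = int(np.argmax(p))  # argmax returns the lowest index on ties
    max_val = float(p[i_star])
    max_pos = float(centers[i_star])
    lo, hi = max(0, i_star - 2), min(p.size, i_star + 3)
    energy_around = float((p[lo:hi] ** 2).sum())
    maxima = local_maxima(p)
    return FirstOrderResult(
        mean=mean, std=std, skewness=skew, kurtosis=kurt, width=width,
        energy=energy, entropy=entropy, maxVal=max_val, maxPos=max_pos,
        energyAroundMax=energy_around, numMaxRel=float(maxima.size),
        energyRelMax=float((p[maxima] ** 2).sum()), degenerate=degenerate,
    )
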