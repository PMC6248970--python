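"""Synthetic phantoms and feature tables with known ground truth.

Two generators make every pipeline stage testable without clinical data:

* ``generate_phantom`` builds a 48^3 CT-like volume with an ellipsoidal
  tumor ROI.  Tumor texture superimposes a two-component blob mixture
  (sharp internal boundaries, heterogeneous) on a smooth drift; the
  per-patient blob strength is drawn from class-specific overlapping
  ranges — high for "adaptive", low-to-zero for "non-adaptive" — so the
  classes differ in texture but not perfectly separably, as in real
  cohorts.  Semantic records are drawn from the cohort's categorical
  frequencies (identical in both classes).

* ``generate_feature_table`` draws a tabular cohort in which k informative
  columns differ between classes by an effect size d (in units of the
  within-class standard deviation) and the rest are pure noise; column
  names follow the real feature registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .data_io import FeatureTable, InputError, VolumeROI
from .registry import registry_names
from .semantic import SemanticRecord

CLASS_ADAPTIVE = "adaptive"
CLASS_NONADAPTIVE = "non-adaptive"


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    Class sizes and the categorical frequencies mirror the 91-patient
    two-class cohort the pipeline targets (50 adaptive / 41 non-adaptive;
    male 76%, stage IIIB 40%, histology 43/47/7/3%, median age 71 with
    spread 9.6 years).  Texture contrast is calibrated so that image
    features separate the classes at pooled-LOO AUC around 0.8-0.9 rather
    than perfectly.
    """

    n_per_class: tuple[int, int] = (50, 41)
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    semi_axis_range: tuple[float, float] = (8.0, 14.0)
    age_center: float = 71.0
    age_sd: float = 9.6
    p_male: float = 0.76
    p_stage_iiib: float = 0.40
    histology_probs: dict[str, float] = field(default_factory=lambda: {
        "adenocarcinoma": 0.43, "squamous": 0.47, "NOS": 0.07, "unavailable": 0.03,
    })
    smoking_probs: dict[str, float] = field(default_factory=lambda: {
        "never": 0.10, "former": 0.50, "current": 0.35, "unknown": 0.05,
    })
    t_probs: tuple[float, ...] = (0.08, 0.22, 0.35, 0.35)   # T1..T4
    n_probs: tuple[float, ...] = (0.10, 0.10, 0.55, 0.25)   # N0..N3
    egfr_probs: dict[str, float] = field(default_factory=lambda: {
        "mutated": 0.10, "wild-type": 0.60, "unknown": 0.30,
    })
    alk_probs: dict[str, float] = field(default_factory=lambda: {
        "rearranged": 0.04, "negative": 0.56, "unknown": 0.40,
    })
    # texture parameters.  Both classes share the generative form
    # base + s*scale*(two-component blobs) + drift + noise; the per-patient
    # heterogeneity strength s is drawn from class-specific overlapping
    # ranges, so texture features separate the classes well but not
    # perfectly (the intended AUC ~0.8-0.9 regime).  A non-adaptive tumor
    # at s=0 is exactly the "single smoothed component" case.
    base_intensity: float = 40.0
    background_mean: float = -50.0
    background_sd: float = 20.0
    noise_sd: float = 3.0
    blob_sigma: float = 1.5          # spatial scale of the two-component blobs
    smooth_sigma: float = 3.0        # spatial scale of the shared smooth drift
    blob_scale_hu: float = 15.0      # HU amplitude of full-strength blobs
    blob_strength_adaptive: tuple[float, float] = (0.3, 1.3)
    blob_strength_nonadaptive: tuple[float, float] = (0.0, 0.85)
    drift_amp_range: tuple[float, float] = (3.0, 7.0)
    # tabular generation
    k_informative: int = 5
    effect_size: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 2 for c in self.n_per_class):
            raise InputError("each class needs at least 2 patients")
        for p in (self.p_male, self.p_stage_iiib):
            if not (0 <= p <= 1):
                raise InputError("proportions must lie in [0, 1]")


def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    pv = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=pv / pv.sum())]


def sample_semantic_record(spec: CohortSpec, rng: np.random.Generator) -> SemanticRecord:
    return SemanticRecord(
        age=float(np.round(rng.normal(spec.age_center, spec.age_sd), 1)),
        sex="M" if rng.random() < spec.p_male else "F",
        smoking=_choice(rng, spec.smoking_probs),
        T=int(1 + rng.choice(4, p=np.array(spec.t_probs) / sum(spec.t_probs))),
        N=int(rng.choice(4, p=np.array(spec.n_probs) / sum(spec.n_probs))),
        stage="IIIB" if rng.random() < spec.p_stage_iiib else "IIIA",
        histology=_choice(rng, spec.histology_probs),
        egfr=_choice(rng, spec.egfr_probs),
        alk=_choice(rng, spec.alk_probs),
    )


def generate_phantom(class_label: str, spec: CohortSpec | None = None,
                     seed: int = 0, patient_id: str | None = None
                     ) -> tuple[VolumeROI, SemanticRecord]:
    """One phantom volume + ROI + semantic record for the given class."""
    spec = spec or CohortSpec()
    if class_label not in (CLASS_ADAPTIVE, CLASS_NONADAPTIVE):
        raise InputError(f"class label must be {CLASS_ADAPTIVE!r} or {CLASS_NONADAPTIVE!r}")
    rng = np.random.default_rng(seed)
    shape = spec.volume_shape
    vol = rng.normal(spec.background_mean, spec.background_sd, shape)

    lo, hi = spec.semi_axis_range
    axes = rng.uniform(lo, hi, size=3)
    center = np.array(shape) / 2.0 + rng.uniform(-3, 3, size=3)
    grid = np.indices(shape).astype(float)
    dist2 = sum(((grid[a] - center[a]) / axes[a]) ** 2 for a in range(3))
    mask = dist2 <= 1.0

    noise = rng.normal(0.0, spec.noise_sd, shape)
    f = gaussian_filter(rng.normal(size=shape), sigma=spec.blob_sigma)
    blobs = (f > np.median(f[mask])).astype(float)
    g = gaussian_filter(rng.normal(size=shape), sigma=spec.smooth_sigma)
    g = g / max(g[mask].std(), 1e-12)
    strength = (spec.blob_strength_adaptive if class_label == CLASS_ADAPTIVE
                else spec.blob_strength_nonadaptive)
    s = rng.uniform(*strength)
    c = s * spec.blob_scale_hu
    a = rng.uniform(*spec.drift_amp_range)
    tumor = spec.base_intensity + c * (blobs - 0.5) + a * g + noise
    vol[mask] = tumor[mask]

    pid = patient_id or f"synthetic-{class_label}-{seed}"
    record = sample_semantic_record(spec, rng)
    return VolumeROI(patient_id=pid, volume=vol, mask=mask), record


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0
                    ) -> list[tuple[VolumeROI, SemanticRecord, str]]:
    """Full two-class phantom cohort (class sizes from the spec)."""
    spec = spec or CohortSpec()
    out = []
    k = 0
    for label, n in zip((CLASS_ADAPTIVE, CLASS_NONADAPTIVE), spec.n_per_class):
        for _ in range(n):
            roi, rec = generate_phantom(label, spec, seed=seed * 100003 + k,
                                        patient_id=f"P{k:03d}")
            out.append((roi, rec, label))
            k += 1
    return out


def generate_feature_table(n: int, p: int, k_informative: int, d: float,
                           class_balance: float = 50 / 91, seed: int = 0
                           ) -> tuple[FeatureTable, list[str]]:
    """Tabular cohort: k informative columns at effect size d, the rest noise.

    Informative columns are N(0,1) in the non-adaptive class and N(d,1) in
    the adaptive class.  Column names are drawn from the real feature
    registry.  Returns the table and the informative column names.
    """
    if k_informative > p:
        raise InputError("k_informative cannot exceed p")
    if n < 4:
        raise InputError("need at least 4 rows")
    rng = np.random.default_rng(seed)
    all_names = registry_names()
    if p > len(all_names):
        raise InputError(f"at most {len(all_names)} named features available")
    names = [all_names[j] for j in sorted(rng.choice(len(all_names), size=p, replace=False))]
    informative = sorted(rng.choice(p, size=k_informative, replace=False))

    n_pos = int(round(n * class_balance))
    n_pos = min(max(n_pos, 2), n - 2)
    labels = np.array([CLASS_ADAPTIVE] * n_pos + [CLASS_NONADAPTIVE] * (n - n_pos),
                      dtype=object)
    X = rng.normal(size=(n, p))
    for j in informative:
        X[:n_pos, j] += d
    table = FeatureTable(
        feature_names=names,
        X=X,
        labels=labels,
        patient_ids=[f"S{i:03d}" for i in range(n)],
        class_values=(CLASS_ADAPTIVE, CLASS_NONADAPTIVE),
    )
    return table, [names[j] for j in informative]
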