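"""Pipeline orchestration: extract -> assemble -> select -> evaluate.

These functions back the command-line interface but are equally usable from
Python.  A run manifest records the resolved configuration, input
checksums, seeds and per-stage wall-times so a run can be reproduced
exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .data_io import FeatureTable, InputError, RunConfig, VolumeROI
from .evaluate import EvaluationReport, RFParams, bootstrap_632plus, compute_metrics, loo_predict
from .registry import extract_features, registry_names
from .selection import SelectionReport, loo_wrapper_selection, positive_class_of
from .semantic import SemanticRecord

ABLATIONS = {
    "full": ("firstorder", "glcm", "lbptop", "semantic"),
    "no-semantic": ("firstorder", "glcm", "lbptop"),
    "no-glcm": ("firstorder", "lbptop", "semantic"),
    "no-lbp": ("firstorder", "glcm", "semantic"),
    "only-semantic": ("semantic",),
}


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: list[str] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    version: str = __version__

    def add_input(self, path: str) -> None:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        self.inputs[str(path)] = h.hexdigest()

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "version": self.version,
                "config": self.config,
                "inputs": self.inputs,
                "outputs": self.outputs,
                "stage_seconds": self.stage_seconds,
            }, fh, indent=1)


def build_feature_table(patients: list[tuple[VolumeROI, SemanticRecord | None, str]],
                        config: RunConfig | None = None) -> FeatureTable:
    """Extract the full registry vector for every patient and assemble the table.

    Any per-patient extraction failure aborts the run naming the patient.
    """
    config = config or RunConfig()
    if not patients:
        raise InputError("need at least one volume/mask pair")
    with_semantic = patients[0][1] is not None
    names = registry_names() if with_semantic else registry_names(("firstorder", "glcm", "lbptop"))
    rows, labels, ids = [], [], []
    for roi, record, label in patients:
        try:
            feats = extract_features(roi, record, G=config.quantization_levels,
                                     firstorder_bins=config.firstorder_bins)
        except Exception as exc:
            raise InputError(f"feature extraction failed for patient {roi.patient_id!r}: {exc}") from exc
        rows.append([feats[n] for n in names])
        labels.append(label)
        ids.append(roi.patient_id)
    # a partial cohort may hold a single class; keep the standard vocabulary
    standard = {"adaptive", "non-adaptive"}
    class_values = ("adaptive", "non-adaptive") if set(labels) <= standard else None
    return FeatureTable(
        feature_names=list(names),
        X=np.array(rows, dtype=float),
        labels=np.array(labels, dtype=object),
        patient_ids=ids,
        class_values=class_values,
    )


def apply_ablation(table: FeatureTable, ablation: str) -> FeatureTable:
    """Drop a feature family before selection, mirroring the ablation rows."""
    if ablation not in ABLATIONS:
        raise InputError(f"unknown ablation {ablation!r}; choose from {sorted(ABLATIONS)}")
    families = ABLATIONS[ablation]
    prefixes = {"firstorder": "stat_", "glcm": "glcm_", "lbptop": "lbp_", "semantic": "sem_"}
    keep_pref = tuple(prefixes[f] for f in families)
    keep = [n for n in table.feature_names if n.startswith(keep_pref)]
    if not keep:
        raise InputError(f"ablation {ablation!r} leaves no features")
    return table.select(keep)


def run_selection_and_evaluation(table: FeatureTable, config: RunConfig | None = None,
                                 ablation: str = "full",
                                 ) -> tuple[SelectionReport, EvaluationReport, RunManifest]:
    """Select the signature on a feature table, then evaluate it by LOO + .632+.

    The ablated family (if any) is removed before selection and the same
    threshold tau applies.
    """
    config = config or RunConfig()
    manifest = RunManifest(config=config.__dict__.copy())
    work = apply_ablation(table, ablation)

    t0 = time.perf_counter()
    report = loo_wrapper_selection(work, tau=config.selection_threshold,
                                   n_trees=config.rf_wrapper_trees, seed=config.seed,
                                   cv_repeats=config.wrapper_cv_repeats)
    manifest.stage_seconds["selection"] = time.perf_counter() - t0

    signature = report.signature
    if not signature:
        # no feature cleared the threshold; fall back to the most frequent one
        best = max(report.frequencies.items(), key=lambda kv: (kv[1], -work.feature_names.index(kv[0])))
        signature = [best[0]]

    rf = RFParams(n_trees=config.rf_trees, max_features=config.rf_max_features,
                  seed=config.seed)
    t0 = time.perf_counter()
    probs = loo_predict(work, signature, rf)
    evaluation = compute_metrics(probs, work.labels, positive_class_of(work),
                                 prevalence=config.prevalence)
    manifest.stage_seconds["loo_evaluation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    boot = bootstrap_632plus(work, signature, rf, B=config.bootstrap_replicates)
    evaluation.b632plus_error = boot.value
    manifest.stage_seconds["bootstrap632plus"] = time.perf_counter() - t0
    manifest.config["ablation"] = ablation
    return report, evaluation, manifest
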