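"""Encoding of the nine clinician-scored semantic features.

Personal data (age, sex, smoking attitude), tumor staging scores (T, N,
overall stage) and tissue characterisation (histology, EGFR and ALK status)
are mapped to a fixed-order numeric vector.  Integer coding (not one-hot)
is used because the downstream learner is tree-based; ordinal fields keep
their natural order and "unknown" is a sentinel value, not a missing entry.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_io import InputError

SEMANTIC_FEATURE_NAMES = [
    "sem_age", "sem_sex", "sem_smoking", "sem_T", "sem_N", "sem_stage",
    "sem_histology", "sem_egfr", "sem_alk",
]

SEX_CODES = {"M": 0, "F": 1}
SMOKING_CODES = {"never": 0, "former": 1, "current": 2, "unknown": -1}
STAGE_CODES = {"IIIA": 0, "IIIB": 1}
HISTOLOGY_CODES = {"adenocarcinoma": 0, "squamous": 1, "NOS": 2, "unavailable": 3}
EGFR_CODES = {"mutated": 1, "wild-type": 0, "unknown": -1}
ALK_CODES = {"rearranged": 1, "negative": 0, "unknown": -1}

_T_VALUES = (1, 2, 3, 4)
_N_VALUES = (0, 1, 2, 3)


@dataclass(frozen=True)
class SemanticRecord:
    age: float
    sex: str
    smoking: str
    T: int
    N: int
    stage: str
    histology: str
    egfr: str
    alk: str


def _code(field: str, value, table: dict) -> int:
    if value not in table:
        raise InputError(
            f"semantic field {field!r}: value {value!r} not in {sorted(table)}"
        )
    return table[value]


def encode_semantic(rec: SemanticRecord) -> dict[str, float]:
    """Numeric encoding of a semantic record, keyed by the fixed feature names."""
    if rec.T not in _T_VALUES:
        raise InputError(f"semantic field 'T': value {rec.T!r} not in {_T_VALUES}")
    if rec.N not in _N_VALUES:
        raise InputError(f"semantic field 'N': value {rec.N!r} not in {_N_VALUES}")
    vals = (
        float(rec.age),
        float(_code("sex", rec.sex, SEX_CODES)),
        float(_code("smoking", rec.smoking, SMOKING_CODES)),
        float(rec.T),
        float(rec.N),
        float(_code("stage", rec.stage, STAGE_CODES)),
        float(_code("histology", rec.histology, HISTOLOGY_CODES)),
        float(_code("egfr", rec.egfr, EGFR_CODES)),
        float(_code("alk", rec.alk, ALK_CODES)),
    )
    return dict(zip(SEMANTIC_FEATURE_NAMES, vals))
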