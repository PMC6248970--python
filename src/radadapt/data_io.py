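"""Input/output layer: volumes with ROI masks, feature tables, run configuration.

Volumes are accepted as NIfTI-1 (via nibabel) or NRRD (via SimpleITK).
Feature tables travel as ARFF (the Weka dialect: ``@relation`` /
``@attribute`` / ``@data`` with a nominal class attribute) or as plain CSV
with a header row and a label column named ``class``.  The ARFF dialect is
small and fully specified, so it is parsed and emitted directly here.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import numpy as np


class InputError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VolumeROI:
    """A 3D scalar volume with an aligned binary region-of-interest mask.

    The mask restricts every feature computation; intensities are
    Hounsfield-unit-like scalars on the voxel grid as stored (0-based
    indices, axis order (x, y, z)).  ``voxel_spacing`` is informational
    only — no resampling is performed.
    """

    patient_id: str
    volume: np.ndarray
    mask: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            mask = mask > 0
        self.mask = mask
        if self.volume.ndim != 3:
            raise InputError(f"volume must be 3D, got shape {self.volume.shape}")
        if self.volume.shape != self.mask.shape:
            raise InputError(
                "volume/mask dimension mismatch: volume "
                f"{self.volume.shape} vs mask {self.mask.shape}"
            )
        n_fg = int(self.mask.sum())
        if n_fg < 2:
            raise InputError(
                f"ROI mask must contain at least 2 foreground voxels, got {n_fg}"
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise InputError(f"voxel spacing must be positive, got {self.voxel_spacing}")

    @property
    def n_roi_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FeatureTable:
    """n patients x named features, plus a binary class label per row.

    ``X`` is an (n, p) float array; NaN marks a missing value, permitted
    only in semantic (``sem_``-prefixed) or nominal-coded columns.  Labels
    take exactly two values (``adaptive`` / ``non-adaptive`` in the target
    application, but any two-value vocabulary read from a file is kept).
    """

    feature_names: list[str]
    X: np.ndarray
    labels: np.ndarray
    patient_ids: list[str]
    class_values: tuple[str, str] | None = None
    nominal_codings: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2:
            raise InputError(f"feature matrix must be 2D, got shape {self.X.shape}")
        if len(self.feature_names) != self.X.shape[1]:
            raise InputError(
                f"{len(self.feature_names)} feature names for {self.X.shape[1]} columns"
            )
        if len(self.labels) != self.X.shape[0]:
            raise InputError(f"{len(self.labels)} labels for {self.X.shape[0]} rows")
        if len(self.patient_ids) != self.X.shape[0]:
            raise InputError("patient_ids length does not match row count")
        uniq = sorted({str(v) for v in self.labels})
        if self.class_values is None:
            if len(uniq) != 2:
                raise InputError(f"labels must take exactly 2 values, got {uniq}")
            self.class_values = (uniq[0], uniq[1])
        else:
            extra = set(uniq) - set(self.class_values)
            if extra or len(self.class_values) != 2:
                raise InputError(
                    f"labels outside the permitted class values {self.class_values}: {sorted(extra)}"
                )
        self._check_missing()

    def _check_missing(self) -> None:
        nan_cols = np.where(np.isnan(self.X).any(axis=0))[0]
        for j in nan_cols:
            name = self.feature_names[j]
            if not (name.startswith("sem_") or name in self.nominal_codings):
                raise InputError(
                    f"missing values are only allowed in semantic features, found NaN in {name!r}"
                )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def select(self, names: list[str]) -> "FeatureTable":
        """Return a copy restricted to the named feature columns, in the given order."""
        idx = []
        lookup = {n: j for j, n in enumerate(self.feature_names)}
        for n in names:
            if n not in lookup:
                raise InputError(f"unknown feature name {n!r}")
            idx.append(lookup[n])
        return FeatureTable(
            feature_names=list(names),
            X=self.X[:, idx].copy(),
            labels=self.labels.copy(),
            patient_ids=list(self.patient_ids),
            class_values=self.class_values,
            nominal_codings={k: v for k, v in self.nominal_codings.items() if k in names},
        )

    def drop(self, names: list[str] | set[str]) -> "FeatureTable":
        keep = [n for n in self.feature_names if n not in set(names)]
        return self.select(keep)

    def subset_rows(self, rows: np.ndarray) -> "FeatureTable":
        rows = np.asarray(rows)
        return FeatureTable(
            feature_names=list(self.feature_names),
            X=self.X[rows].copy(),
            labels=self.labels[rows].copy(),
            patient_ids=[self.patient_ids[i] for i in np.arange(self.n)[rows]],
            class_values=self.class_values,
            nominal_codings=dict(self.nominal_codings),
        )


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Attributes
    ----------
    quantization_levels : gray-level alphabet size G for texture features.
    lbp_radii : sampling radii for the three-orthogonal-plane LBP family.
    selection_threshold : minimum selection frequency tau for the signature.
    rf_trees : tree count of the final random forest.
    rf_wrapper_trees : tree count of the forest inside the wrapper objective.
    wrapper_cv_repeats : repeated stratified 2-fold splits averaged by the
        wrapper objective.
    rf_max_features : split-candidate count m; None means floor(sqrt(p)),
        always kept strictly below the feature count p.
    bootstrap_replicates : replicate count B of the .632+ bootstrap.
    prevalence : assumed positive-class prevalence pi for adjusted PPV/NPV.
    """

    quantization_levels: int = 32
    lbp_radii: tuple[int, ...] = (1, 2, 3)
    firstorder_bins: int = 64
    selection_threshold: float = 0.10
    rf_trees: int = 500
    rf_wrapper_trees: int = 100
    wrapper_cv_repeats: int = 5
    rf_max_features: int | None = None
    bootstrap_replicates: int = 200
    prevalence: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.selection_threshold <= 1):
            raise InputError("selection threshold tau must lie in (0, 1]")
        if self.bootstrap_replicates < 2:
            raise InputError("bootstrap replicate count B must be >= 2")
        if not (0 < self.prevalence < 1):
            raise InputError("assumed prevalence pi must lie in (0, 1)")
        if self.quantization_levels < 2:
            raise InputError("quantization level count G must be >= 2")


# ---------------------------------------------------------------------------
# Volume reading
# ---------------------------------------------------------------------------

def _load_volume(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    p = str(path)
    if p.endswith(".nii") or p.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(p)
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()[:3]
        return data, tuple(float(z) for z in zooms)
    if p.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(p)
        # SimpleITK arrays come back (z, y, x); store as (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
        return data, tuple(float(s) for s in img.GetSpacing())
    raise InputError(f"unsupported volume format: {p} (expected .nii, .nii.gz or .nrrd)")


def read_volume_roi(volume_path: str, mask_path: str, patient_id: str | None = None) -> VolumeROI:
    """Read a volume and its binary ROI mask; mask values are coerced by ``> 0``."""
    vol, spacing = _load_volume(volume_path)
    mask, _ = _load_volume(mask_path)
    if vol.shape != mask.shape:
        raise InputError(
            f"volume/mask dimension mismatch: volume {vol.shape} vs mask {mask.shape}"
        )
    pid = patient_id if patient_id is not None else str(volume_path)
    return VolumeROI(patient_id=pid, volume=vol, mask=mask > 0, voxel_spacing=spacing)


def write_volume_nifti(array: np.ndarray, path: str, spacing=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# ARFF (Weka dialect)
# ---------------------------------------------------------------------------

_ARFF_QUOTE_NEEDED = re.compile(r"[\s,{}%'\"]")


def _arff_quote(name: str) -> str:
    if _ARFF_QUOTE_NEEDED.search(name):
        return "'" + name.replace("\\", "\\\\").replace("'", "\\'") + "'"
    return name


def _split_arff_line(line: str) -> list[str]:
    """Split a @data line on commas, honouring single/double quotes."""
    out, buf, quote, i = [], [], None, 0
    while i < len(line):
        c = line[i]
        if quote:
            if c == "\\" and i + 1 < len(line):
                buf.append(line[i + 1])
                i += 2
                continue
            if c == quote:
                quote = None
            else:
                buf.append(c)
        elif c in ("'", '"'):
            quote = c
        elif c == ",":
            out.append("".join(buf).strip())
            buf = []
        else:
            buf.append(c)
        i += 1
    out.append("".join(buf).strip())
    return out


def _parse_arff_attribute(rest: str) -> tuple[str, str | list[str]]:
    """Parse the remainder of an @attribute line -> (name, 'numeric' | nominal values)."""
    rest = rest.strip()
    if rest.startswith(("'", '"')):
        q = rest[0]
        j, buf = 1, []
        while j < len(rest):
            if rest[j] == "\\" and j + 1 < len(rest):
                buf.append(rest[j + 1])
                j += 2
                continue
            if rest[j] == q:
                break
            buf.append(rest[j])
            j += 1
        name = "".join(buf)
        spec = rest[j + 1:].strip()
    else:
        parts = rest.split(None, 1)
        if len(parts) != 2:
            raise InputError(f"malformed @attribute line: {rest!r}")
        name, spec = parts[0], parts[1].strip()
    if spec.startswith("{"):
        if not spec.endswith("}"):
            raise InputError(f"malformed nominal specification for {name!r}")
        values = [v.strip().strip("'\"") for v in _split_arff_line(spec[1:-1])]
        return name, values
    kind = spec.split()[0].lower()
    if kind in ("numeric", "real", "integer"):
        return name, "numeric"
    if kind == "string":
        return name, "string"
    raise InputError(f"unsupported ARFF attribute type {spec!r} for {name!r}")


def _read_arff(path: str, class_attr: str | None) -> FeatureTable:
    attrs: list[tuple[str, str | list[str]]] = []
    data_rows: list[list[str]] = []
    in_data = False
    with open(path, "r") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if in_data:
                data_rows.append(_split_arff_line(line))
            elif low.startswith("@attribute"):
                attrs.append(_parse_arff_attribute(line[len("@attribute"):]))
            elif low.startswith("@data"):
                in_data = True
            elif low.startswith("@relation"):
                continue
            else:
                raise InputError(f"unrecognised ARFF header line: {line!r}")
    if not attrs:
        raise InputError(f"no @attribute declarations found in {path}")

    names = [a[0] for a in attrs]
    if class_attr is None:
        lowered = [n.lower() for n in names]
        if "class" in lowered:
            class_attr = names[lowered.index("class")]
        else:
            nominal = [n for n, s in attrs if isinstance(s, list)]
            if not nominal:
                raise InputError("no nominal class attribute found")
            class_attr = nominal[-1]
    ci = names.index(class_attr)
    class_spec = attrs[ci][1]
    if not isinstance(class_spec, list):
        raise InputError(f"class attribute {class_attr!r} is not nominal")
    if len(class_spec) != 2:
        raise InputError(
            f"class attribute must have exactly 2 values, got {len(class_spec)}: {class_spec}"
        )

    feat_idx = [j for j in range(len(attrs)) if j != ci]
    codings: dict[str, dict[str, int]] = {}
    for j in feat_idx:
        nm, spec = attrs[j]
        if isinstance(spec, list):
            codings[nm] = {v: k for k, v in enumerate(spec)}

    X = np.empty((len(data_rows), len(feat_idx)))
    labels = []
    for r, row in enumerate(data_rows):
        if len(row) != len(attrs):
            raise InputError(
                f"ARFF data row {r} has {len(row)} values, expected {len(attrs)}"
            )
        lab = row[ci]
        if lab not in class_spec:
            raise InputError(f"row {r}: class value {lab!r} not in {class_spec}")
        labels.append(lab)
        for k, j in enumerate(feat_idx):
            nm, spec = attrs[j]
            tok = row[j]
            if tok == "?":
                X[r, k] = np.nan
            elif isinstance(spec, list):
                if tok not in codings[nm]:
                    raise InputError(f"row {r}: value {tok!r} not in nominal domain of {nm!r}")
                X[r, k] = codings[nm][tok]
            else:
                try:
                    X[r, k] = float(tok)
                except ValueError:
                    raise InputError(
                        f"row {r}: non-numeric value {tok!r} in numeric attribute {nm!r}"
                    ) from None
    return FeatureTable(
        feature_names=[names[j] for j in feat_idx],
        X=X,
        labels=np.array(labels, dtype=object),
        patient_ids=[f"row{r}" for r in range(len(data_rows))],
        class_values=(class_spec[0], class_spec[1]),
        nominal_codings=codings,
    )


def _write_arff(table: FeatureTable, path: str, relation: str = "radadapt") -> None:
    inv_codings = {
        name: {code: val for val, code in coding.items()}
        for name, coding in table.nominal_codings.items()
    }
    with open(path, "w") as fh:
        fh.write(f"@relation {relation}\n\n")
        for name in table.feature_names:
            if name in table.nominal_codings:
                vals = [v for v, _ in sorted(table.nominal_codings[name].items(), key=lambda kv: kv[1])]
                fh.write(f"@attribute {_arff_quote(name)} {{{','.join(_arff_quote(v) for v in vals)}}}\n")
            else:
                fh.write(f"@attribute {_arff_quote(name)} numeric\n")
        cv = table.class_values
        fh.write(f"@attribute class {{{_arff_quote(cv[0])},{_arff_quote(cv[1])}}}\n")
        fh.write("\n@data\n")
        for r in range(table.n):
            toks = []
            for j, name in enumerate(table.feature_names):
                v = table.X[r, j]
                if np.isnan(v):
                    toks.append("?")
                elif name in inv_codings:
                    toks.append(_arff_quote(inv_codings[name][int(v)]))
                else:
                    toks.append(repr(float(v)))
            toks.append(_arff_quote(str(table.labels[r])))
            fh.write(",".join(toks) + "\n")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: str, label_column: str = "class") -> FeatureTable:
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = [row for row in reader if row]
    if label_column not in header:
        raise InputError(f"CSV is missing the label column {label_column!r}")
    ci = header.index(label_column)
    has_id = header[0] == "patient_id"
    feat_idx = [j for j in range(len(header)) if j != ci and not (has_id and j == 0)]
    names = [header[j] for j in feat_idx]
    labels = [row[ci] for row in rows]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise InputError(f"label column must have exactly 2 distinct values, got {uniq}")
    X = np.empty((len(rows), len(feat_idx)))
    for r, row in enumerate(rows):
        if len(row) != len(header):
            raise InputError(f"CSV row {r} has {len(row)} fields, expected {len(header)}")
        for k, j in enumerate(feat_idx):
            tok = row[j].strip()
            if tok in ("", "?", "NA", "nan"):
                X[r, k] = np.nan
            else:
                try:
                    X[r, k] = float(tok)
                except ValueError:
                    raise InputError(
                        f"row {r}: non-numeric value {tok!r} in column {header[j]!r}"
                    ) from None
    ids = [row[0] for row in rows] if has_id else [f"row{r}" for r in range(len(rows))]
    return FeatureTable(
        feature_names=names,
        X=X,
        labels=np.array(labels, dtype=object),
        patient_ids=ids,
        class_values=(uniq[0], uniq[1]),
    )


def _write_csv(table: FeatureTable, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id"] + list(table.feature_names) + ["class"])
        for r in range(table.n):
            row = [table.patient_ids[r]]
            for v in table.X[r]:
                row.append("?" if np.isnan(v) else repr(float(v)))
            row.append(str(table.labels[r]))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Public feature-table API
# ---------------------------------------------------------------------------

def _infer_dialect(path: str, dialect: str | None) -> str:
    if dialect is not None:
        d = dialect.upper()
        if d not in ("ARFF", "CSV"):
            raise InputError(f"unknown dialect {dialect!r}")
        return d
    p = str(path).lower()
    if p.endswith(".arff"):
        return "ARFF"
    if p.endswith(".csv"):
        return "CSV"
    raise InputError(f"cannot infer table dialect from {path!r}; pass dialect=")


def read_feature_table(path: str, dialect: str | None = None,
                       class_attr: str | None = None) -> FeatureTable:
    """Read a feature table from ARFF or CSV; feature order is preserved as in the file."""
    d = _infer_dialect(path, dialect)
    if d == "ARFF":
        return _read_arff(path, class_attr)
    return _read_csv(path, label_column=class_attr or "class")


def write_feature_table(table: FeatureTable, path: str, dialect: str | None = None) -> None:
    """Write a feature table; the output re-reads to equal content (values to 1e-9)."""
    if table.p == 0:
        raise InputError("refusing to write a table with an empty feature list")
    d = _infer_dialect(path, dialect)
    if d == "ARFF":
        _write_arff(table, path)
    else:
        _write_csv(table, path)
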