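"""Clinical cohort containers, the index schema, and CSV I/O.

A cohort is a patients x indexes matrix with a +/-1 outcome label per
patient: +1 means portal vein system thrombosis (PVST) developed after
splenectomy with cardia devascularization, -1 means it did not.  Clinical
indexes are either boolean (gender, the two antithrombotic therapy flags)
or continuous lab values.  Measurable lab indexes are recorded repeatedly
after the operation; per patient they collapse to the median of all
recorded values.  Age and bleeding volume pass through unchanged.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureDef",
    "CohortSchema",
    "RawPatientRecord",
    "ClinicalCohort",
    "SchemaError",
    "MissingValueError",
    "default_schema",
    "encode_boolean",
    "build_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_long_csv",
]


class SchemaError(ValueError):
    """A feature name/id does not belong to the declared schema."""


class MissingValueError(ValueError):
    """A patient has no recorded value for a required feature."""


@dataclass(frozen=True)
class FeatureDef:
    """One clinical index: integer id, name, value kind, and whether it is
    a static (countable) index or a repeatedly measured lab value."""

    id: int
    name: str
    kind: str = "continuous"  # "boolean" | "continuous"
    static: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("boolean", "continuous"):
            raise SchemaError(f"unknown feature kind {self.kind!r}")


class CohortSchema:
    """Ordered collection of :class:`FeatureDef` with unique ids and names."""

    def __init__(self, features: list[FeatureDef]):
        self.features = list(features)
        ids = [f.id for f in self.features]
        names = [f.name for f in self.features]
        if len(set(ids)) != len(ids) or len(set(names)) != len(names):
            raise SchemaError("feature ids and names must be unique")
        self.by_id = {f.id: f for f in self.features}
        self.by_name = {f.name: f for f in self.features}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def ids(self) -> list[int]:
        return [f.id for f in self.features]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def kinds(self) -> list[str]:
        return [f.kind for f in self.features]


#: Reference 33-index schema: 6 countable indicators (age, gender, weight,
#: bleeding volume and the two therapy flags) plus 27 measurable lab indexes.
_DEFAULT_FEATURES = [
    (1, "Age", "continuous", True),
    (2, "Gender", "boolean", True),
    (3, "Weight", "continuous", True),
    (4, "BV", "continuous", True),
    (5, "AST", "continuous", False),
    (6, "ALT", "continuous", False),
    (7, "CHOL", "continuous", False),
    (8, "TBIL", "continuous", False),
    (9, "DBIL", "continuous", False),
    (10, "TP", "continuous", False),
    (11, "ALB", "continuous", False),
    (12, "BUN", "continuous", False),
    (13, "CRE", "continuous", False),
    (14, "GLU", "continuous", False),
    (15, "Na", "continuous", False),
    (16, "K", "continuous", False),
    (17, "Ca", "continuous", False),
    (18, "RBC", "continuous", False),
    (19, "HGB", "continuous", False),
    (20, "WBC", "continuous", False),
    (21, "LY1", "continuous", False),
    (22, "LY2", "continuous", False),
    (23, "NE1", "continuous", False),
    (24, "NE2", "continuous", False),
    (25, "PLT", "continuous", False),
    (26, "PT", "continuous", False),
    (27, "INR", "continuous", False),
    (28, "APTT", "continuous", False),
    (29, "TT", "continuous", False),
    (30, "FIB", "continuous", False),
    (31, "D-D", "continuous", False),
    (32, "AnticoagulantTherapy", "boolean", True),
    (33, "AntiplateletTherapy", "boolean", True),
]


def default_schema() -> CohortSchema:
    """The reference 33-index clinical schema."""
    return CohortSchema([FeatureDef(i, n, k, s) for i, n, k, s in _DEFAULT_FEATURES])


@dataclass
class RawPatientRecord:
    """Pre-aggregation record for one patient.

    ``static_values`` maps feature name (or id) to the single recorded value;
    ``measurements`` holds ``(feature, iso_date, value)`` triples for the
    repeatedly measured lab indexes.
    """

    patient_id: str
    label: int
    static_values: dict = field(default_factory=dict)
    measurements: list = field(default_factory=list)


# canonical 0/1 encodings for boolean clinical indexes; gender encodes
# male -> 0, female -> 1, therapies encode absent -> 0, given -> 1
_BOOL_ZERO = {"male", "no", "false", "0"}
_BOOL_ONE = {"female", "yes", "true", "1"}


def encode_boolean(value) -> int:
    """Encode a boolean clinical index value as 0/1."""
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        if float(value) in (0.0, 1.0):
            return int(value)
        raise ValueError(f"numeric boolean value must be 0 or 1, got {value!r}")
    if isinstance(value, str):
        v = value.strip().lower()
        if v in _BOOL_ZERO or v.startswith("without"):
            return 0
        if v in _BOOL_ONE or v.startswith("with"):
            return 1
    raise ValueError(f"cannot encode {value!r} as a boolean clinical index")


@dataclass
class ClinicalCohort:
    """Patients x indexes matrix with +/-1 labels and a feature schema."""

    values: np.ndarray
    labels: np.ndarray
    schema: CohortSchema

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d matrix")
        m, n = self.values.shape
        if self.labels.shape != (m,):
            raise ValueError("labels length must match the number of patients")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be +1 (PVST) or -1 (non-PVST)")
        if n != len(self.schema):
            raise ValueError("schema length must match the number of features")
        for j, f in enumerate(self.schema):
            if f.kind == "boolean":
                col = self.values[:, j]
                if not np.all(np.isin(col, (0.0, 1.0))):
                    raise ValueError(f"boolean feature {f.name!r} has values outside {{0,1}}")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[int]:
        return self.schema.ids

    @property
    def feature_names(self) -> list[str]:
        return self.schema.names

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.schema.names)
        df["label"] = self.labels
        return df


def _resolve(schema: CohortSchema, key) -> FeatureDef:
    if isinstance(key, str) and key in schema.by_name:
        return schema.by_name[key]
    if isinstance(key, (int, np.integer)) and int(key) in schema.by_id:
        return schema.by_id[int(key)]
    raise SchemaError(f"feature {key!r} not in schema")


def build_cohort(
    records: list[RawPatientRecord],
    schema: CohortSchema | None = None,
    missing: str = "error",
) -> ClinicalCohort:
    """Collapse raw patient records into a cohort matrix.

    Measurable indexes take the per-patient median of all recorded values
    (permutation-invariant over the measurement list); boolean indexes are
    0/1-encoded; other static indexes pass through unchanged.

    Parameters
    ----------
    missing : {"error", "median"}
        What to do when a patient has no value for a measurable feature:
        raise (default) or impute the across-patient median of that feature.
    """
    if schema is None:
        schema = default_schema()
    if missing not in ("error", "median"):
        raise ValueError("missing must be 'error' or 'median'")
    m, n = len(records), len(schema)
    values = np.full((m, n), np.nan)
    labels = np.empty(m, dtype=int)
    col = {f.id: j for j, f in enumerate(schema)}
    for i, rec in enumerate(records):
        if rec.label not in (-1, 1):
            raise ValueError(f"patient {rec.patient_id!r}: label must be +1 or -1")
        labels[i] = rec.label
        per_feature: dict[int, list[float]] = {}
        for key, date, value in rec.measurements:
            f = _resolve(schema, key)
            datetime.date.fromisoformat(str(date))  # dates must be orderable ISO-8601
            per_feature.setdefault(f.id, []).append(float(value))
        for key, value in rec.static_values.items():
            f = _resolve(schema, key)
            v = encode_boolean(value) if f.kind == "boolean" else float(value)
            values[i, col[f.id]] = v
        for fid, vals in per_feature.items():
            values[i, col[fid]] = float(np.median(vals))
    nan_rows, nan_cols = np.nonzero(np.isnan(values))
    if nan_rows.size:
        if missing == "error":
            i, j = nan_rows[0], nan_cols[0]
            raise MissingValueError(
                f"patient {records[i].patient_id!r} has no value for "
                f"feature {schema.features[j].name!r}"
            )
        for j in np.unique(nan_cols):
            colv = values[:, j]
            fill = np.nanmedian(colv)
            if np.isnan(fill):
                raise MissingValueError(
                    f"feature {schema.features[j].name!r} has no recorded values at all"
                )
            colv[np.isnan(colv)] = fill
    return ClinicalCohort(values, labels, schema)


def read_cohort_csv(path, schema: CohortSchema | None = None) -> ClinicalCohort:
    """Read a wide cohort CSV: one patient per row, feature-name header,
    a ``label`` column in {1, -1}; an optional ``patient_id`` column is
    ignored for the matrix."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise SchemaError("cohort CSV must contain a 'label' column")
    labels = df.pop("label").to_numpy()
    if "patient_id" in df.columns:
        df = df.drop(columns=["patient_id"])
    if schema is None:
        feats = []
        for j, name in enumerate(df.columns, start=1):
            vals = pd.to_numeric(df[name], errors="raise")
            kind = "boolean" if set(np.unique(vals.dropna())) <= {0.0, 1.0} else "continuous"
            feats.append(FeatureDef(j, str(name), kind))
        schema = CohortSchema(feats)
    else:
        unknown = [c for c in df.columns if c not in schema.by_name]
        if unknown:
            raise SchemaError(f"unknown column(s) {unknown} not in schema")
        missing = [nm for nm in schema.names if nm not in df.columns]
        if missing:
            raise SchemaError(f"schema feature(s) {missing} missing from CSV")
        df = df[schema.names]
    values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    return ClinicalCohort(values, labels, schema)


def write_cohort_csv(cohort: ClinicalCohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_long_csv(path, schema: CohortSchema | None = None) -> list[RawPatientRecord]:
    """Read long-format raw records: columns patient_id, label, feature,
    date, value.  Rows for static features (empty date) go to
    ``static_values``; dated rows become measurements."""
    if schema is None:
        schema = default_schema()
    df = pd.read_csv(path, dtype={"patient_id": str, "feature": str})
    required = {"patient_id", "label", "feature", "value"}
    if not required <= set(df.columns):
        raise SchemaError(f"long CSV must contain columns {sorted(required)}")
    records = []
    for pid, grp in df.groupby("patient_id", sort=False):
        lab = grp["label"].unique()
        if len(lab) != 1:
            raise ValueError(f"patient {pid!r} has inconsistent labels")
        rec = RawPatientRecord(patient_id=str(pid), label=int(lab[0]))
        for _, row in grp.iterrows():
            f = _resolve(schema, row["feature"])
            date = row.get("date")
            if f.static or (isinstance(date, float) and np.isnan(date)) or date in ("", None):
                rec.static_values[f.name] = row["value"]
            else:
                rec.measurements.append((f.name, str(date), float(row["value"])))
        records.append(rec)
    return records
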