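"""Domain types, validation, and delimited-text I/O for study tables.

All tables are plain CSV (comma, decimal point, UTF-8, mandatory header).
Missing values are empty cells on disk; ``NA``/``NaN`` are accepted
case-insensitively on input. Floats are written with ``%.12g`` so that a
write → read → write cycle is byte-stable after the first pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_TYPES",
    "CONDITIONS",
    "TIMEPOINTS",
    "TIMEPOINT_CLOCK_HOURS",
    "SCALE_TAGS",
    "ValidationError",
    "DataError",
    "ConfigError",
    "SampleRecord",
    "FeatureTable",
    "validate_records",
    "records_to_frame",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_feature_table",
    "write_feature_table",
    "write_table",
]

SAMPLE_TYPES = ("study", "qc_pool", "blank", "dilution")
CONDITIONS = ("control", "sleep_deprivation")
TIMEPOINTS = ("t1", "t2", "t3", "t4", "t5", "t6", "t7")
SCALE_TAGS = ("raw", "corrected", "log10", "zscore")

#: Canonical sampling clock times, in hours since midnight of study day 1
#: (day 1: 20:30; day 2: 22:55; day 3: 08:10, 13:55, 21:00, 22:55;
#: day 4: 08:10).
TIMEPOINT_CLOCK_HOURS = {
    "t1": 20.0 + 30.0 / 60.0,
    "t2": 24.0 + 22.0 + 55.0 / 60.0,
    "t3": 48.0 + 8.0 + 10.0 / 60.0,
    "t4": 48.0 + 13.0 + 55.0 / 60.0,
    "t5": 48.0 + 21.0,
    "t6": 48.0 + 22.0 + 55.0 / 60.0,
    "t7": 72.0 + 8.0 + 10.0 / 60.0,
}

FLOAT_FMT = "%.12g"

_NA_STRINGS = {"", "na", "nan"}


class ValidationError(ValueError):
    """A record or table violates a structural invariant."""


class DataError(ValueError):
    """The data are structurally valid but unusable for the requested step."""


class ConfigError(ValueError):
    """A configuration value is out of range or inconsistent."""


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for a single injection."""

    sample_id: str
    sample_type: str
    run_order: int
    batch: int = 1
    subject_id: str | None = None
    condition: str | None = None
    timepoint: str | None = None
    dilution_fraction: float | None = None
    clock_hour: float | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown sample_type {self.sample_type!r}"
            )
        if not isinstance(self.run_order, (int, np.integer)) or self.run_order < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: run_order must be a positive integer"
            )
        if not isinstance(self.batch, (int, np.integer)) or self.batch < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: batch must be a positive integer"
            )
        if self.sample_type == "study":
            missing = [
                name
                for name, val in (
                    ("subject_id", self.subject_id),
                    ("condition", self.condition),
                    ("timepoint", self.timepoint),
                )
                if val is None
            ]
            if missing:
                raise ValidationError(
                    f"study sample {self.sample_id!r} lacks {', '.join(missing)}"
                )
            if self.condition not in CONDITIONS:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown condition {self.condition!r}"
                )
            if self.timepoint not in TIMEPOINTS:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown timepoint {self.timepoint!r}"
                )
        else:
            for name, val in (
                ("subject_id", self.subject_id),
                ("condition", self.condition),
                ("timepoint", self.timepoint),
            ):
                if val is not None:
                    raise ValidationError(
                        f"{self.sample_type} sample {self.sample_id!r} must not set {name}"
                    )
        if (self.dilution_fraction is not None) != (self.sample_type == "dilution"):
            raise ValidationError(
                f"sample {self.sample_id!r}: dilution_fraction present iff "
                "sample_type is 'dilution'"
            )
        if self.dilution_fraction is not None and not (0.0 < self.dilution_fraction <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id!r}: dilution_fraction must lie in (0, 1]"
            )
        if self.clock_hour is not None and self.clock_hour < 0:
            raise ValidationError(f"sample {self.sample_id!r}: clock_hour must be >= 0")


def validate_records(records: Sequence[SampleRecord]) -> None:
    """Check cross-record invariants (uniqueness of ids, run orders, cells)."""
    seen_ids: dict[str, str] = {}
    for rec in records:
        if rec.sample_id in seen_ids:
            raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
        seen_ids[rec.sample_id] = rec.sample_id

    by_run: dict[int, list[str]] = {}
    for rec in records:
        by_run.setdefault(rec.run_order, []).append(rec.sample_id)
    dups = {k: v for k, v in by_run.items() if len(v) > 1}
    if dups:
        parts = [f"run_order {k}: {', '.join(v)}" for k, v in sorted(dups.items())]
        raise ValidationError("duplicate run_order values — " + "; ".join(parts))

    cells: dict[tuple[str, str, str], list[str]] = {}
    for rec in records:
        if rec.sample_type == "study":
            key = (rec.subject_id, rec.condition, rec.timepoint)  # type: ignore[arg-type]
            cells.setdefault(key, []).append(rec.sample_id)
    bad = {k: v for k, v in cells.items() if len(v) > 1}
    if bad:
        parts = [f"{k}: {', '.join(v)}" for k, v in sorted(bad.items())]
        raise ValidationError(
            "duplicated (subject, condition, timepoint) cells — " + "; ".join(parts)
        )


METADATA_COLUMNS = [
    "sample_id",
    "sample_type",
    "subject_id",
    "condition",
    "timepoint",
    "run_order",
    "batch",
    "dilution_fraction",
    "clock_hour",
]


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "sample_id": rec.sample_id,
                "sample_type": rec.sample_type,
                "subject_id": rec.subject_id if rec.subject_id is not None else "",
                "condition": rec.condition if rec.condition is not None else "",
                "timepoint": rec.timepoint if rec.timepoint is not None else "",
                "run_order": rec.run_order,
                "batch": rec.batch,
                "dilution_fraction": rec.dilution_fraction,
                "clock_hour": rec.clock_hour,
            }
        )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def _parse_optional_str(value: object) -> str | None:
    if value is None:
        return None
    text = str(value).strip()
    if text.lower() in _NA_STRINGS:
        return None
    return text


def _parse_optional_float(value: object, *, where: str) -> float | None:
    text = _parse_optional_str(value)
    if text is None:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(f"{where}: cannot parse {text!r} as a number") from exc


def read_sample_metadata(path) -> list[SampleRecord]:
    """Read and validate a sample-metadata CSV.

    Enum-like fields are parsed case-insensitively; empty cells denote
    absent optional fields.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValidationError(
            f"metadata file {path} lacks columns: {', '.join(missing_cols)}"
        )
    records: list[SampleRecord] = []
    for idx, row in frame.iterrows():
        sample_id = str(row["sample_id"]).strip()
        where = f"metadata row {idx + 2} (sample {sample_id!r})"
        sample_type = (_parse_optional_str(row["sample_type"]) or "").lower()
        condition = _parse_optional_str(row["condition"])
        timepoint = _parse_optional_str(row["timepoint"])
        run_order = _parse_optional_float(row["run_order"], where=where)
        batch = _parse_optional_float(row["batch"], where=where)
        if run_order is None or batch is None:
            raise ValidationError(f"{where}: run_order and batch are mandatory")
        records.append(
            SampleRecord(
                sample_id=sample_id,
                sample_type=sample_type,
                subject_id=_parse_optional_str(row["subject_id"]),
                condition=condition.lower() if condition is not None else None,
                timepoint=timepoint.lower() if timepoint is not None else None,
                run_order=int(run_order),
                batch=int(batch),
                dilution_fraction=_parse_optional_float(
                    row["dilution_fraction"], where=where
                ),
                clock_hour=_parse_optional_float(row["clock_hour"], where=where),
            )
        )
    validate_records(records)
    return records


def write_sample_metadata(records: Sequence[SampleRecord], path) -> None:
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, float_format=FLOAT_FMT, na_rep="")


@dataclass
class FeatureTable:
    """A features × injections abundance matrix with explicit missingness.

    ``values`` holds floats with ``NaN`` marking missing cells. On the
    ``raw`` and ``corrected`` scales all non-missing values must be
    non-negative.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in SCALE_TAGS:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features × {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        if self.scale_tag in ("raw", "corrected"):
            bad = np.argwhere(np.nan_to_num(self.values, nan=0.0) < 0)
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"negative value at feature {self.feature_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r} on scale {self.scale_tag!r}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.feature_ids), list(self.sample_ids), self.values.copy(),
            self.scale_tag,
        )

    def with_values(self, values: np.ndarray, scale_tag: str | None = None) -> "FeatureTable":
        return FeatureTable(
            list(self.feature_ids), list(self.sample_ids), values,
            scale_tag if scale_tag is not None else self.scale_tag,
        )

    def subset(
        self,
        feature_ids: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> "FeatureTable":
        """Restrict to the given features and/or samples, keeping order."""
        f_keep = set(feature_ids) if feature_ids is not None else None
        s_keep = set(sample_ids) if sample_ids is not None else None
        f_idx = [
            i for i, f in enumerate(self.feature_ids) if f_keep is None or f in f_keep
        ]
        s_idx = [
            j for j, s in enumerate(self.sample_ids) if s_keep is None or s in s_keep
        ]
        return FeatureTable(
            [self.feature_ids[i] for i in f_idx],
            [self.sample_ids[j] for j in s_idx],
            self.values[np.ix_(f_idx, s_idx)],
            self.scale_tag,
        )

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def read_feature_table(
    path, metadata: Sequence[SampleRecord], scale_tag: str = "raw"
) -> FeatureTable:
    """Read a feature abundance CSV (rows = features, columns = samples)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.columns[0] != "feature_id":
        raise ValidationError(
            f"feature table {path}: first column must be 'feature_id', "
            f"got {frame.columns[0]!r}"
        )
    known = {rec.sample_id for rec in metadata}
    unknown = [c for c in frame.columns[1:] if c not in known]
    if unknown:
        raise ValidationError(
            f"feature table {path}: sample columns not in metadata: "
            + ", ".join(unknown)
        )
    feature_ids = [str(v) for v in frame["feature_id"]]
    sample_ids = list(frame.columns[1:])
    raw = frame.iloc[:, 1:].to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            text = str(raw[i, j]).strip()
            if text.lower() in _NA_STRINGS:
                values[i, j] = np.nan
                continue
            try:
                val = float(text)
            except ValueError as exc:
                raise ValidationError(
                    f"feature {feature_ids[i]!r}, sample {sample_ids[j]!r}: "
                    f"cannot parse {text!r}"
                ) from exc
            if scale_tag in ("raw", "corrected") and val < 0:
                raise ValidationError(
                    f"negative value {val} at feature {feature_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            values[i, j] = val
    return FeatureTable(feature_ids, sample_ids, values, scale_tag)


def write_feature_table(table: FeatureTable, path) -> None:
    frame = table.to_frame()
    frame.to_csv(path, float_format=FLOAT_FMT, na_rep="")


def write_table(obj, path) -> None:
    """Write any supported table object to CSV with deterministic layout."""
    if isinstance(obj, FeatureTable):
        write_feature_table(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False, float_format=FLOAT_FMT, na_rep="")
    elif isinstance(obj, (list, tuple)) and all(
        isinstance(r, SampleRecord) for r in obj
    ):
        write_sample_metadata(obj, path)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
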