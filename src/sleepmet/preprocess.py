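"""QC-anchored drift correction, quality filtering, imputation, log10.

Pipeline order is fixed: ``correct_drift`` → ``compute_feature_qc`` /
``filter_features`` → ``filter_subjects`` → ``impute_lod`` →
``log_transform``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .studydata import (
    ConfigError,
    DataError,
    FeatureTable,
    SampleRecord,
)

__all__ = [
    "FilterThresholds",
    "DriftCorrection",
    "correct_drift",
    "compute_feature_qc",
    "filter_features",
    "filter_subjects",
    "impute_lod",
    "log_transform",
    "PreprocessResult",
    "run_preprocessing",
]

logger = logging.getLogger(__name__)

QC_REPORT_COLUMNS = [
    "feature_id",
    "blank_ratio",
    "blank_detected",
    "rsd_qc_pct",
    "dilution_r2",
    "d_ratio_pct",
    "missing_fraction",
    "pass_blank",
    "pass_rsd",
    "pass_dilution",
    "pass_dratio",
    "pass_missing",
    "keep",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Quality-filter cut-offs. All comparisons against them are strict
    in the removal direction (e.g. RSD exactly at the maximum is kept)."""

    rsd_max_pct: float = 25.0
    r2_min: float = 0.7
    d_ratio_max_pct: float = 50.0
    missing_max_fraction: float = 0.30
    blank_ratio_max: float = 0.05

    def validate(self) -> None:
        if self.rsd_max_pct < 0:
            raise ConfigError("rsd_max_pct must be >= 0")
        if not (0.0 <= self.r2_min <= 1.0):
            raise ConfigError("r2_min must lie in [0, 1]")
        if self.d_ratio_max_pct < 0:
            raise ConfigError("d_ratio_max_pct must be >= 0")
        if not (0.0 <= self.missing_max_fraction <= 1.0):
            raise ConfigError("missing_max_fraction must lie in [0, 1]")
        if self.blank_ratio_max < 0:
            raise ConfigError("blank_ratio_max must be >= 0")


def _cols_of_type(samples: Sequence[SampleRecord], sample_ids, sample_type: str):
    pos = {s: j for j, s in enumerate(sample_ids)}
    return [
        pos[r.sample_id]
        for r in samples
        if r.sample_type == sample_type and r.sample_id in pos
    ]


class DriftCorrection(NamedTuple):
    table: FeatureTable
    passthrough_features: list


def correct_drift(
    table: FeatureTable,
    samples: Sequence[SampleRecord],
    window: int = 8,
) -> DriftCorrection:
    """Remove run-order drift per feature and batch using QC-pool anchors.

    A tricube-weighted local linear regression of QC abundances against
    run order (span chosen so ~``window`` QC points carry weight) is
    interpolated to every injection's run order; extrapolation beyond the
    first/last QC injection is clamped to the edge fit. Each value is
    multiplied by ``median(QC)/trend`` so the corrected QC level is flat.
    Features with fewer than two usable QC values in a batch pass through
    unchanged and are reported.
    """
    if table.scale_tag != "raw":
        raise DataError(f"correct_drift expects a raw-scale table, got {table.scale_tag!r}")
    if window < 2:
        raise ConfigError("window must be >= 2")
    rec_by_id = {r.sample_id: r for r in samples}
    missing_meta = [s for s in table.sample_ids if s not in rec_by_id]
    if missing_meta:
        raise DataError(f"samples without metadata: {', '.join(missing_meta)}")
    qc_cols_all = _cols_of_type(samples, table.sample_ids, "qc_pool")
    if not qc_cols_all:
        raise DataError(
            "no QC pool samples present — drift correction impossible; "
            "skip the correction step explicitly if this is intended"
        )

    run_orders = np.array([rec_by_id[s].run_order for s in table.sample_ids], dtype=float)
    batches = np.array([rec_by_id[s].batch for s in table.sample_ids])
    corrected = table.values.copy()
    passthrough: set = set()

    for batch in np.unique(batches):
        in_batch = np.where(batches == batch)[0]
        qc_cols = [j for j in qc_cols_all if batches[j] == batch]
        if len(qc_cols) < 2:
            passthrough.update(table.feature_ids)
            continue
        qc_runs = run_orders[qc_cols]
        order = np.argsort(qc_runs)
        qc_runs = qc_runs[order]
        qc_cols = [qc_cols[k] for k in order]
        batch_runs = run_orders[in_batch]
        for i, fid in enumerate(table.feature_ids):
            y = table.values[i, qc_cols]
            ok = np.isfinite(y)
            if ok.sum() < 2:
                passthrough.add(fid)
                continue
            x = qc_runs[ok]
            yy = y[ok]
            frac = min(1.0, max(window, 2) / ok.sum())
            fit = lowess(yy, x, frac=frac, it=0, return_sorted=True)
            # clamp trend away from zero so corrections stay finite/positive
            med = float(np.median(yy))
            trend = np.interp(batch_runs, fit[:, 0], fit[:, 1])
            trend = np.maximum(trend, 1e-3 * abs(med) if med != 0 else 1e-12)
            corrected[i, in_batch] = table.values[i, in_batch] * med / trend
    out = table.with_values(corrected, scale_tag="corrected")
    return DriftCorrection(out, sorted(passthrough))


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def compute_feature_qc(
    table: FeatureTable,
    samples: Sequence[SampleRecord],
    thresholds: FilterThresholds | None = None,
    robust_dratio: bool = False,
) -> pd.DataFrame:
    """Per-feature quality metrics and pass/fail flags.

    Metrics that cannot be evaluated (fewer than 3 usable points, zero
    denominators) are recorded as NaN; their pass flags are False (the
    default drop policy — ``filter_features`` can re-resolve them).
    """
    thr = thresholds if thresholds is not None else FilterThresholds()
    thr.validate()
    qc_cols = _cols_of_type(samples, table.sample_ids, "qc_pool")
    blank_cols = _cols_of_type(samples, table.sample_ids, "blank")
    dil_cols = _cols_of_type(samples, table.sample_ids, "dilution")
    study_cols = _cols_of_type(samples, table.sample_ids, "study")
    rec_by_id = {r.sample_id: r for r in samples}
    dil_fracs = np.array(
        [rec_by_id[table.sample_ids[j]].dilution_fraction for j in dil_cols], dtype=float
    )

    rows = []
    for i, fid in enumerate(table.feature_ids):
        vals = table.values[i]
        qc = vals[qc_cols]
        qc = qc[np.isfinite(qc)]
        study = vals[study_cols]
        study_ok = study[np.isfinite(study)]

        blank = np.nan_to_num(vals[blank_cols], nan=0.0)
        mean_blank = float(blank.mean()) if blank.size else 0.0
        mean_qc = float(qc.mean()) if qc.size else 0.0
        if mean_qc > 0:
            blank_ratio = mean_blank / mean_qc
        else:
            blank_ratio = np.inf if mean_blank > 0 else 0.0

        if qc.size >= 3 and mean_qc != 0.0:
            rsd = 100.0 * _sd(qc) / mean_qc
        else:
            rsd = np.nan

        dil = vals[dil_cols]
        ok = np.isfinite(dil)
        if ok.sum() >= 3:
            x = dil_fracs[ok]
            yv = dil[ok]
            if np.std(x) > 0 and np.std(yv) > 0:
                r = np.corrcoef(x, yv)[0, 1]
                r2 = float(r * r)
            else:
                r2 = np.nan
        else:
            r2 = np.nan

        if robust_dratio:
            qc_spread = 1.4826 * float(np.median(np.abs(qc - np.median(qc)))) if qc.size >= 3 else np.nan
            st_spread = (
                1.4826 * float(np.median(np.abs(study_ok - np.median(study_ok))))
                if study_ok.size >= 3
                else np.nan
            )
        else:
            qc_spread = _sd(qc) if qc.size >= 3 else np.nan
            st_spread = _sd(study_ok) if study_ok.size >= 3 else np.nan
        if np.isfinite(qc_spread) and np.isfinite(st_spread) and st_spread > 0:
            d_ratio = 100.0 * qc_spread / st_spread
        else:
            d_ratio = np.nan

        n_study = len(study_cols)
        miss = (
            float((~np.isfinite(study) | (study == 0)).sum()) / n_study
            if n_study
            else np.nan
        )

        rows.append(
            {
                "feature_id": fid,
                "blank_ratio": blank_ratio,
                "rsd_qc_pct": rsd,
                "dilution_r2": r2,
                "d_ratio_pct": d_ratio,
                "missing_fraction": miss,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["feature_id", "blank_ratio", "rsd_qc_pct", "dilution_r2",
                 "d_ratio_pct", "missing_fraction"],
    )
    _apply_flags(report, thr, policy_undefined="drop")
    return report[QC_REPORT_COLUMNS]


def _apply_flags(report: pd.DataFrame, thr: FilterThresholds, policy_undefined: str) -> None:
    if policy_undefined not in ("drop", "keep"):
        raise ConfigError(f"policy_undefined must be 'drop' or 'keep', got {policy_undefined!r}")
    und = policy_undefined == "keep"

    def resolve(series: pd.Series, passes: pd.Series) -> pd.Series:
        return passes.where(series.notna(), other=und)

    report["blank_detected"] = report["blank_ratio"] > thr.blank_ratio_max
    report["pass_blank"] = ~report["blank_detected"].astype(bool)
    report["pass_rsd"] = resolve(
        report["rsd_qc_pct"], report["rsd_qc_pct"] <= thr.rsd_max_pct
    )
    report["pass_dilution"] = resolve(
        report["dilution_r2"], report["dilution_r2"] >= thr.r2_min
    )
    report["pass_dratio"] = resolve(
        report["d_ratio_pct"], report["d_ratio_pct"] <= thr.d_ratio_max_pct
    )
    report["pass_missing"] = resolve(
        report["missing_fraction"], report["missing_fraction"] <= thr.missing_max_fraction
    )
    report["keep"] = (
        report["pass_blank"]
        & report["pass_rsd"]
        & report["pass_dilution"]
        & report["pass_dratio"]
        & report["pass_missing"]
    )


def filter_features(
    report: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    policy_undefined: str = "drop",
) -> list:
    """Feature ids that pass every quality criterion."""
    thr = thresholds if thresholds is not None else FilterThresholds()
    thr.validate()
    out = report.copy()
    _apply_flags(out, thr, policy_undefined)
    return out.loc[out["keep"], "feature_id"].tolist()


def filter_subjects(
    table: FeatureTable,
    samples: Sequence[SampleRecord],
    missing_max_fraction: float = 0.30,
) -> list:
    """Subject ids whose missing-or-zero fraction over study cells is
    at most the threshold (strictly-more-than rule drops)."""
    if not (0.0 <= missing_max_fraction <= 1.0):
        raise ConfigError("missing_max_fraction must lie in [0, 1]")
    pos = {s: j for j, s in enumerate(table.sample_ids)}
    by_subject: dict[str, list[int]] = {}
    for rec in samples:
        if rec.sample_type == "study" and rec.sample_id in pos:
            by_subject.setdefault(rec.subject_id, []).append(pos[rec.sample_id])  # type: ignore[arg-type]
    kept = []
    for subj in sorted(by_subject):
        block = table.values[:, by_subject[subj]]
        frac = float((~np.isfinite(block) | (block == 0)).mean())
        if frac <= missing_max_fraction:
            kept.append(subj)
        else:
            logger.info("subject %s dropped: %.1f%% missing/zero", subj, 100 * frac)
    if len(kept) < 3:
        raise DataError(
            f"only {len(kept)} subjects remain after the missingness filter; "
            "at least 3 are required for within-subject statistics"
        )
    return kept


class ImputeResult(NamedTuple):
    table: FeatureTable
    n_replaced: int


def impute_lod(table: FeatureTable, samples: Sequence[SampleRecord]) -> ImputeResult:
    """Replace missing/zero study values with 1/5 of the feature's lowest
    positive detected study value."""
    study_cols = _cols_of_type(samples, table.sample_ids, "study")
    values = table.values.copy()
    n_replaced = 0
    for i, fid in enumerate(table.feature_ids):
        study = values[i, study_cols]
        positive = study[np.isfinite(study) & (study > 0)]
        need = ~np.isfinite(study) | (study == 0)
        if need.any():
            if positive.size == 0:
                raise DataError(
                    f"feature {fid!r} has no positive study value to derive the "
                    "imputation floor — it should have been filtered out"
                )
            fill = float(positive.min()) / 5.0
            study = study.copy()
            study[need] = fill
            values[i, study_cols] = study
            n_replaced += int(need.sum())
    return ImputeResult(table.with_values(values), n_replaced)


def log_transform(table: FeatureTable, samples: Sequence[SampleRecord]) -> FeatureTable:
    """Elementwise log10 of study, QC and dilution values; blank
    injections are dropped from the output table."""
    rec_by_id = {r.sample_id: r for r in samples}
    keep_cols = [
        j for j, s in enumerate(table.sample_ids)
        if rec_by_id[s].sample_type != "blank"
    ]
    values = table.values[:, keep_cols]
    sample_ids = [table.sample_ids[j] for j in keep_cols]
    bad = np.argwhere(np.isfinite(values) & (values <= 0))
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"non-positive value at feature {table.feature_ids[i]!r}, "
            f"sample {sample_ids[j]!r}: impute before log-transforming"
        )
    out = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    out[mask] = np.log10(values[mask])
    return FeatureTable(list(table.feature_ids), sample_ids, out, scale_tag="log10")


@dataclass
class PreprocessResult:
    corrected: FeatureTable
    passthrough_features: list
    qc_report: pd.DataFrame
    kept_features: list
    kept_subjects: list
    n_imputed: int
    table_log10: FeatureTable
    samples: list


def run_preprocessing(
    table: FeatureTable,
    samples: Sequence[SampleRecord],
    thresholds: FilterThresholds | None = None,
    window: int = 8,
    policy_undefined: str = "drop",
    skip_drift: bool = False,
) -> PreprocessResult:
    """Run the full fixed-order preprocessing pipeline."""
    thr = thresholds if thresholds is not None else FilterThresholds()
    if skip_drift:
        corrected = table.with_values(table.values.copy(), scale_tag="corrected")
        passthrough: list = []
    else:
        corrected, passthrough = correct_drift(table, samples, window=window)
    report = compute_feature_qc(corrected, samples, thr)
    kept_features = filter_features(report, thr, policy_undefined)
    sub = corrected.subset(feature_ids=kept_features)
    kept_subjects = filter_subjects(sub, samples, thr.missing_max_fraction)
    keep_samples = [
        r for r in samples
        if r.sample_type != "study" or r.subject_id in set(kept_subjects)
    ]
    sub = sub.subset(sample_ids=[r.sample_id for r in keep_samples])
    imputed, n_replaced = impute_lod(sub, keep_samples)
    logged = log_transform(imputed, keep_samples)
    logger.info(
        "preprocessing: %d/%d features kept, %d/%d subjects kept, %d values imputed",
        len(kept_features), table.n_features, len(kept_subjects),
        len({r.subject_id for r in samples if r.sample_type == "study"}), n_replaced,
    )
    return PreprocessResult(
        corrected=corrected,
        passthrough_features=list(passthrough),
        qc_report=report,
        kept_features=kept_features,
        kept_subjects=kept_subjects,
        n_imputed=n_replaced,
        table_log10=logged,
        samples=[r for r in keep_samples if r.sample_type != "blank"],
    )
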