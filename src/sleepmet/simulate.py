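"""Synthetic crossover sleep-study datasets with known ground truth.

The generative model works on the log10 scale. For a study sample

    y = baseline + subject_offset + rhythm + condition_effect + noise

with a cosine diurnal rhythm, an additive condition effect whose shape
depends on the planted feature class, and a multiplicative linear
run-order drift applied after exponentiation. QC pools, a process blank
and two dilution series bracket the randomized study injections, with a
QC pool every ``qc_every`` study injections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .studydata import (
    CONDITIONS,
    TIMEPOINT_CLOCK_HOURS,
    TIMEPOINTS,
    ConfigError,
    FeatureTable,
    SampleRecord,
    validate_records,
)

__all__ = [
    "FEATURE_CLASSES",
    "SLEEP_CLASSES",
    "SimConfig",
    "SyntheticTruth",
    "hours_awake",
    "generate_dataset",
    "truth_to_frame",
]

FEATURE_CLASSES = (
    "null",
    "sleep_linear",
    "sleep_rhythmic",
    "non_adaptive",
    "non_robust",
    "contaminant",
)
#: Classes whose condition effect is genuinely sleep-related.
SLEEP_CLASSES = ("sleep_linear", "sleep_rhythmic")

WAKE_HOUR = 7.5   # habitual wake time 07:30
BED_HOUR = 23.5   # habitual bedtime 23:30

# Wake anchors in hours since midnight of day 1. Under deprivation the
# day-3 wake (hour 55.5) is skipped: subjects stay awake from the day-2
# wake until the recovery night.
_WAKES_CONTROL = (WAKE_HOUR, WAKE_HOUR + 24.0, WAKE_HOUR + 48.0, WAKE_HOUR + 72.0)
_WAKES_DEPRIVED = (WAKE_HOUR, WAKE_HOUR + 24.0, WAKE_HOUR + 72.0)

#: Hours of wakefulness at which the deprivation effect reaches full size.
MAX_WAKE_HOURS = 40.0


def hours_awake(timepoint: str, condition: str) -> float:
    """Hours of sustained wakefulness at a sampling time point."""
    if timepoint not in TIMEPOINTS:
        raise ConfigError(f"unknown timepoint {timepoint!r}")
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    clock = TIMEPOINT_CLOCK_HOURS[timepoint]
    anchors = _WAKES_CONTROL if condition == "control" else _WAKES_DEPRIVED
    last_wake = max(a for a in anchors if a <= clock)
    return clock - last_wake


@dataclass
class SimConfig:
    """Parameters of the synthetic study. All sds are in log10 units."""

    n_subjects: int = 13
    n_features: int = 100
    class_mix: dict = field(
        default_factory=lambda: {
            "null": 0.40,
            "sleep_linear": 0.15,
            "sleep_rhythmic": 0.15,
            "non_adaptive": 0.10,
            "non_robust": 0.10,
            "contaminant": 0.10,
        }
    )
    subject_sd: float = 0.35
    residual_sd: float = 0.08
    technical_sd_qc: float = 0.04
    baseline_range: tuple = (3.5, 6.0)
    rhythm_amplitude_range: tuple = (0.05, 0.25)
    effect_size_range: tuple = (0.2, 0.5)
    drift_slope_range: tuple = (-0.3, 0.3)
    acrophase_range: tuple = (14.0, 22.0)
    lod_quantile: float = 0.05
    qc_every: int = 5
    dilution_fractions: tuple = (1.0, 0.5, 0.2, 0.1)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError("n_subjects must be >= 3")
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        unknown = set(self.class_mix) - set(FEATURE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown feature classes in class_mix: {unknown}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_mix sums to {total}, expected 1")
        if any(v < 0 for v in self.class_mix.values()):
            raise ConfigError("class_mix proportions must be non-negative")
        for name in (
            "rhythm_amplitude_range",
            "effect_size_range",
            "drift_slope_range",
            "baseline_range",
            "acrophase_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name}: lower bound exceeds upper bound")
        for name in ("subject_sd", "residual_sd", "technical_sd_qc"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.lod_quantile < 1.0):
            raise ConfigError("lod_quantile must lie in [0, 1)")
        if self.qc_every < 1:
            raise ConfigError("qc_every must be >= 1")
        if any(not (0.0 < f <= 1.0) for f in self.dilution_fractions):
            raise ConfigError("dilution_fractions must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Per-feature generative parameters of a simulated dataset."""

    feature_ids: list
    subject_ids: list
    true_class: np.ndarray          # str array, n_features
    baseline_mu: np.ndarray         # log10 units
    amplitude: np.ndarray
    acrophase_hour: np.ndarray      # in [0, 24)
    effect_delta: np.ndarray        # log10 units, 0 for null/contaminant
    drift_slope: np.ndarray
    lod_threshold: np.ndarray       # raw scale
    subject_offsets: np.ndarray     # n_features × n_subjects, log10 units


def truth_to_frame(truth: SyntheticTruth) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "feature_id": truth.feature_ids,
            "true_class": truth.true_class,
            "baseline_mu": truth.baseline_mu,
            "amplitude": truth.amplitude,
            "acrophase_hour": truth.acrophase_hour,
            "effect_delta": truth.effect_delta,
            "drift_slope": truth.drift_slope,
            "lod_threshold": truth.lod_threshold,
        }
    )
    for j, subj in enumerate(truth.subject_ids):
        frame[f"offset_{subj}"] = truth.subject_offsets[:, j]
    return frame


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder apportionment, then a seeded shuffle."""
    classes = [c for c in FEATURE_CLASSES if cfg.class_mix.get(c, 0.0) > 0]
    quotas = np.array([cfg.class_mix[c] * cfg.n_features for c in classes])
    counts = np.floor(quotas).astype(int)
    remainder = cfg.n_features - counts.sum()
    order = np.argsort(-(quotas - counts))
    for k in range(remainder):
        counts[order[k % len(classes)]] += 1
    labels = np.repeat(classes, counts)
    return rng.permutation(labels)


def _effect_multiplier(feature_class: str, timepoint: str, condition: str) -> float:
    """Unit-effect shape; multiplied by the feature's effect_delta."""
    if condition == "control" or feature_class in ("null", "contaminant"):
        return 0.0
    if feature_class == "sleep_linear":
        if timepoint in ("t3", "t4", "t5", "t6"):
            return (hours_awake(timepoint, condition) - 15.0) / 25.0
        return 0.0
    if feature_class == "sleep_rhythmic":
        return 1.0 if timepoint == "t3" else 0.0
    if feature_class == "non_adaptive":
        return 1.0 if timepoint in ("t3", "t4", "t5", "t6", "t7") else 0.0
    if feature_class == "non_robust":
        return 1.0
    raise ConfigError(f"unknown feature class {feature_class!r}")


def _build_sample_records(cfg: SimConfig, rng: np.random.Generator) -> list[SampleRecord]:
    subjects = [f"sub{k + 1:02d}" for k in range(cfg.n_subjects)]
    study_keys = [
        (subj, cond, tp) for subj in subjects for cond in CONDITIONS for tp in TIMEPOINTS
    ]
    study_keys = [study_keys[i] for i in rng.permutation(len(study_keys))]

    records: list[SampleRecord] = []
    run = 0
    qc_n = 0

    def add_qc() -> None:
        nonlocal run, qc_n
        run += 1
        qc_n += 1
        records.append(
            SampleRecord(sample_id=f"qc{qc_n:03d}", sample_type="qc_pool", run_order=run)
        )

    def add_dilution(tag: str) -> None:
        nonlocal run
        for k, frac in enumerate(cfg.dilution_fractions):
            run += 1
            records.append(
                SampleRecord(
                    sample_id=f"dil_{tag}_{k + 1}",
                    sample_type="dilution",
                    run_order=run,
                    dilution_fraction=float(frac),
                )
            )

    run += 1
    records.append(SampleRecord(sample_id="blank01", sample_type="blank", run_order=run))
    add_dilution("start")
    add_qc()
    for i, (subj, cond, tp) in enumerate(study_keys):
        run += 1
        cond_tag = "ctl" if cond == "control" else "dep"
        records.append(
            SampleRecord(
                sample_id=f"{subj}_{cond_tag}_{tp}",
                sample_type="study",
                run_order=run,
                subject_id=subj,
                condition=cond,
                timepoint=tp,
                clock_hour=TIMEPOINT_CLOCK_HOURS[tp],
            )
        )
        if (i + 1) % cfg.qc_every == 0:
            add_qc()
    if records[-1].sample_type != "qc_pool":
        add_qc()
    add_dilution("end")
    validate_records(records)
    return records


def generate_dataset(
    cfg: SimConfig,
) -> tuple[FeatureTable, list[SampleRecord], SyntheticTruth]:
    """Simulate a raw feature table, its metadata, and the ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nf = cfg.n_features

    true_class = _assign_classes(cfg, rng)
    baseline = rng.uniform(*cfg.baseline_range, size=nf)
    amplitude = rng.uniform(*cfg.rhythm_amplitude_range, size=nf)
    acrophase = np.mod(rng.uniform(*cfg.acrophase_range, size=nf), 24.0)
    effect = rng.uniform(*cfg.effect_size_range, size=nf)
    effect[np.isin(true_class, ("null", "contaminant"))] = 0.0
    slope = rng.uniform(*cfg.drift_slope_range, size=nf)
    subjects = [f"sub{k + 1:02d}" for k in range(cfg.n_subjects)]
    offsets = rng.normal(0.0, cfg.subject_sd, size=(nf, cfg.n_subjects))

    records = _build_sample_records(cfg, rng)
    n_samples = len(records)
    run_orders = np.array([rec.run_order for rec in records], dtype=float)
    mid = (run_orders.min() + run_orders.max()) / 2.0
    span = max(run_orders.max() - run_orders.min(), 1.0)
    # multiplicative linear drift, clipped away from zero
    drift = np.clip(1.0 + slope[:, None] * (run_orders[None, :] - mid) / span, 0.1, None)

    day_hours = np.array([TIMEPOINT_CLOCK_HOURS[tp] % 24.0 for tp in TIMEPOINTS])
    mean_cos = np.cos(
        2.0 * np.pi * (day_hours[None, :] - acrophase[:, None]) / 24.0
    ).mean(axis=1)
    qc_base = 10.0 ** (baseline + amplitude * mean_cos)

    subj_index = {s: j for j, s in enumerate(subjects)}
    values = np.full((nf, n_samples), np.nan)

    study_cols = [j for j, r in enumerate(records) if r.sample_type == "study"]
    qc_cols = [j for j, r in enumerate(records) if r.sample_type == "qc_pool"]
    blank_cols = [j for j, r in enumerate(records) if r.sample_type == "blank"]
    dil_cols = [j for j, r in enumerate(records) if r.sample_type == "dilution"]

    mult = np.empty((nf, len(study_cols)))
    rhythm = np.empty((nf, len(study_cols)))
    subj_off = np.empty((nf, len(study_cols)))
    for k, j in enumerate(study_cols):
        rec = records[j]
        hour_of_day = rec.clock_hour % 24.0  # type: ignore[operator]
        rhythm[:, k] = amplitude * np.cos(
            2.0 * np.pi * (hour_of_day - acrophase) / 24.0
        )
        subj_off[:, k] = offsets[:, subj_index[rec.subject_id]]
        mult[:, k] = [
            _effect_multiplier(c, rec.timepoint, rec.condition) for c in true_class
        ]
    noise = rng.normal(0.0, cfg.residual_sd, size=(nf, len(study_cols)))
    y = baseline[:, None] + subj_off + rhythm + effect[:, None] * mult + noise
    values[:, study_cols] = 10.0 ** y * drift[:, study_cols]

    qc_noise = 10.0 ** rng.normal(0.0, cfg.technical_sd_qc, size=(nf, len(qc_cols)))
    values[:, qc_cols] = qc_base[:, None] * drift[:, qc_cols] * qc_noise

    blank_vals = np.zeros((nf, len(blank_cols)))
    contaminant = true_class == "contaminant"
    if contaminant.any():
        blank_noise = 10.0 ** rng.normal(
            0.0, cfg.technical_sd_qc, size=(int(contaminant.sum()), len(blank_cols))
        )
        blank_vals[contaminant, :] = (
            0.5 * qc_base[contaminant, None] * blank_noise
        )
    values[:, blank_cols] = blank_vals * drift[:, blank_cols]

    dil_frac = np.array([records[j].dilution_fraction for j in dil_cols], dtype=float)
    dil_noise = 10.0 ** rng.normal(0.0, cfg.technical_sd_qc, size=(nf, len(dil_cols)))
    values[:, dil_cols] = (
        qc_base[:, None] * dil_frac[None, :] * drift[:, dil_cols] * dil_noise
    )

    # LOD censoring: per-feature threshold at the lod_quantile of that
    # feature's study values; strictly smaller study values become missing.
    study_vals = values[:, study_cols]
    if cfg.lod_quantile > 0.0:
        lod = np.quantile(study_vals, cfg.lod_quantile, axis=1)
        censored = study_vals < lod[:, None]
        study_vals = study_vals.copy()
        study_vals[censored] = np.nan
        values[:, study_cols] = study_vals
    else:
        lod = np.min(study_vals, axis=1)

    feature_ids = [f"F{k + 1:04d}" for k in range(nf)]
    sample_ids = [rec.sample_id for rec in records]
    table = FeatureTable(feature_ids, sample_ids, values, scale_tag="raw")
    truth = SyntheticTruth(
        feature_ids=feature_ids,
        subject_ids=subjects,
        true_class=true_class,
        baseline_mu=baseline,
        amplitude=amplitude,
        acrophase_hour=acrophase,
        effect_delta=effect,
        drift_slope=slope,
        lod_threshold=lod,
        subject_offsets=offsets,
    )
    return table, records, truth
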