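"""Per-timepoint paired testing between conditions and time-course
profile classification.

A feature is classified from its seven per-timepoint paired-test
p-values, in strict rule order:

1. significant at t1 or t2            → ``non_robust``
2. else significant at t7             → ``non_adaptive``
3. else significant at all of t3–t6   → ``sleep_linear``
4. else significant at any of t3–t6   → ``sleep_rhythmic``
5. else                               → ``unaffected``

Gate timepoints t1/t2 precede the experimental night and t7 follows the
recovery night, so a genuine sleep effect must be absent there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .studydata import DataError, FeatureTable, SampleRecord, TIMEPOINTS

__all__ = [
    "CATEGORIES",
    "GATE_TIMEPOINTS",
    "EFFECT_TIMEPOINTS",
    "PairedTestResult",
    "paired_tests",
    "classify_profile",
    "classify_profiles",
    "compound_fp_rate",
    "summarize_classification",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("non_robust", "non_adaptive", "sleep_linear", "sleep_rhythmic", "unaffected")
GATE_TIMEPOINTS = ("t1", "t2", "t7")
EFFECT_TIMEPOINTS = ("t3", "t4", "t5", "t6")
MIN_PAIRS = 3


@dataclass
class PairedTestResult:
    """Per-(feature, timepoint) paired t-test results in matrix layout.

    Each frame is indexed by feature_id with columns t1..t7. ``p`` is NaN
    where fewer than :data:`MIN_PAIRS` complete pairs exist; ``degenerate``
    marks cells where the difference variance was zero but the mean was
    not (p reported as 0).
    """

    alpha: float
    n_pairs: pd.DataFrame
    mean_diff: pd.DataFrame
    t_stat: pd.DataFrame
    df: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    degenerate: pd.DataFrame


def paired_tests(
    table: FeatureTable, samples: Sequence[SampleRecord], alpha: float = 0.01
) -> PairedTestResult:
    """Two-sided paired t-tests (deprivation − control) per timepoint.

    Subjects lacking either condition's value at a timepoint are dropped
    pairwise for that cell.
    """
    if not (0.0 < alpha < 1.0):
        raise DataError("alpha must lie in (0, 1)")
    if table.scale_tag not in ("log10", "zscore"):
        raise DataError("paired_tests expects a log10- or zscore-scale table")
    pos = {s: j for j, s in enumerate(table.sample_ids)}
    subjects = sorted(
        {r.subject_id for r in samples if r.sample_type == "study" and r.sample_id in pos}
    )
    subj_idx = {s: k for k, s in enumerate(subjects)}
    nf = table.n_features

    shape = (nf, len(TIMEPOINTS))
    n_pairs = np.zeros(shape, dtype=int)
    mean_diff = np.full(shape, np.nan)
    t_stat = np.full(shape, np.nan)
    dfs = np.zeros(shape, dtype=int)
    pvals = np.full(shape, np.nan)
    degenerate = np.zeros(shape, dtype=bool)

    for ti, tp in enumerate(TIMEPOINTS):
        ctl = np.full((nf, len(subjects)), np.nan)
        dep = np.full((nf, len(subjects)), np.nan)
        for rec in samples:
            if rec.sample_type != "study" or rec.timepoint != tp:
                continue
            col = pos.get(rec.sample_id)
            if col is None:
                continue
            target = ctl if rec.condition == "control" else dep
            target[:, subj_idx[rec.subject_id]] = table.values[:, col]
        diff = dep - ctl
        ok = np.isfinite(diff)
        n = ok.sum(axis=1)
        n_pairs[:, ti] = n
        dfs[:, ti] = np.maximum(n - 1, 0)
        enough = n >= MIN_PAIRS
        if not enough.any():
            continue
        d = np.where(ok, diff, 0.0)
        md = d.sum(axis=1) / np.maximum(n, 1)
        mean_diff[enough, ti] = md[enough]
        dev = np.where(ok, diff - md[:, None], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (dev**2).sum(axis=1) / np.maximum(n - 1, 1)
            se = np.sqrt(var / np.maximum(n, 1))
            t = md / se
        zero_var = enough & (var == 0)
        finite = enough & (var > 0)
        t_stat[finite, ti] = t[finite]
        pvals[finite, ti] = 2.0 * stats.t.sf(
            np.abs(t[finite]), n[finite] - 1
        )
        # zero-variance differences: all-zero → p = 1; constant ≠ 0 → p = 0
        all_zero = zero_var & (md == 0)
        const = zero_var & (md != 0)
        t_stat[all_zero, ti] = 0.0
        pvals[all_zero, ti] = 1.0
        t_stat[const, ti] = np.inf * np.sign(md[const])
        pvals[const, ti] = 0.0
        degenerate[const, ti] = True

    n_undefined = int((n_pairs < MIN_PAIRS).sum())
    if n_undefined:
        logger.warning(
            "paired_tests: %d (feature, timepoint) cells with < %d pairs "
            "reported undefined", n_undefined, MIN_PAIRS,
        )
    idx = pd.Index(table.feature_ids, name="feature_id")
    cols = list(TIMEPOINTS)

    def frame(arr):
        return pd.DataFrame(arr, index=idx, columns=cols)

    sig = np.where(np.isnan(pvals), False, pvals < alpha)
    return PairedTestResult(
        alpha=alpha,
        n_pairs=frame(n_pairs),
        mean_diff=frame(mean_diff),
        t_stat=frame(t_stat),
        df=frame(dfs),
        p=frame(pvals),
        significant=frame(sig.astype(bool)),
        degenerate=frame(degenerate),
    )


def classify_profile(
    pvals: Mapping[str, float], alpha: float
) -> tuple[str, tuple]:
    """(category, significant timepoints) for one feature.

    Undefined (NaN / absent) p-values count as non-significant.
    """
    sig = tuple(
        tp for tp in TIMEPOINTS
        if tp in pvals and np.isfinite(pvals[tp]) and pvals[tp] < alpha
    )
    sig_set = set(sig)
    if sig_set & {"t1", "t2"}:
        return "non_robust", sig
    if "t7" in sig_set:
        return "non_adaptive", sig
    if sig_set >= set(EFFECT_TIMEPOINTS):
        return "sleep_linear", sig
    if sig_set & set(EFFECT_TIMEPOINTS):
        return "sleep_rhythmic", sig
    return "unaffected", sig


def classify_profiles(tests: PairedTestResult, alpha: float | None = None) -> pd.DataFrame:
    """Classification table for every tested feature."""
    a = alpha if alpha is not None else tests.alpha
    rows = []
    for fid in tests.p.index:
        pv = tests.p.loc[fid].to_dict()
        category, sig = classify_profile(pv, a)
        direction = "none"
        for tp in TIMEPOINTS:
            if tp in sig:
                md = tests.mean_diff.loc[fid, tp]
                if np.isfinite(md) and md != 0:
                    direction = "up" if md > 0 else "down"
                break
        undefined = tests.p.loc[fid].isna().any()
        rows.append(
            {
                "feature_id": fid,
                "category": category,
                "significant_timepoints": "|".join(sig),
                "direction_at_first_hit": direction,
                "quality_flag": "undefined_p" if undefined else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "category",
            "significant_timepoints",
            "direction_at_first_hit",
            "quality_flag",
        ],
    )


def compound_fp_rate(alpha: float, n_gate: int = 3) -> float:
    """Probability that a null feature is significant at one given
    effect timepoint while non-significant at the ``n_gate`` gate
    timepoints: alpha · (1 − alpha)^n_gate."""
    if not (0.0 <= alpha <= 1.0):
        raise DataError("alpha must lie in [0, 1]")
    if n_gate < 0:
        raise DataError("n_gate must be >= 0")
    return alpha * (1.0 - alpha) ** n_gate


def summarize_classification(
    classifications: pd.DataFrame, tests: PairedTestResult | None = None
) -> pd.DataFrame:
    """Long-format summary: category counts/fractions, per-timepoint
    significant counts among t3–t6, multi-timepoint hits, directions."""
    n = len(classifications)
    rows = [{"metric": "n_features", "value": float(n)}]
    for cat in CATEGORIES:
        count = int((classifications["category"] == cat).sum()) if n else 0
        rows.append({"metric": f"count_{cat}", "value": float(count)})
        rows.append({"metric": f"fraction_{cat}", "value": count / n if n else 0.0})
    sleep_n = (
        int(classifications["category"].isin(("sleep_linear", "sleep_rhythmic")).sum())
        if n
        else 0
    )
    rows.append({"metric": "count_sleep_related", "value": float(sleep_n)})
    rows.append({"metric": "fraction_sleep_related", "value": sleep_n / n if n else 0.0})

    sig_sets = [
        set(s.split("|")) if s else set()
        for s in (classifications["significant_timepoints"] if n else [])
    ]
    for tp in EFFECT_TIMEPOINTS:
        count = sum(1 for s in sig_sets if tp in s)
        rows.append({"metric": f"count_significant_{tp}", "value": float(count)})
    multi = sum(1 for s in sig_sets if len(s) >= 2)
    rows.append({"metric": "count_multi_timepoint", "value": float(multi)})
    for direction in ("up", "down", "none"):
        count = (
            int((classifications["direction_at_first_hit"] == direction).sum()) if n else 0
        )
        rows.append({"metric": f"count_direction_{direction}", "value": float(count)})
    return pd.DataFrame(rows, columns=["metric", "value"])
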