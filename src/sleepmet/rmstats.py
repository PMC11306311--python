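"""Subject-wise z-normalization and the fully within-subject two-way
repeated-measures ANOVA (time × sleep) with Greenhouse–Geisser-corrected
p-values and percent-of-total-variation decomposition.

The ANOVA runs on complete balanced blocks over the four post-night
time levels (t3–t6) and the two sleep conditions. Error terms are the
classical effect-by-subject interactions:

    F_time  = MS_time  / MS_time×subject
    F_sleep = MS_sleep / MS_sleep×subject
    F_int   = MS_int   / MS_time×sleep×subject
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .studydata import DataError, FeatureTable, SampleRecord

__all__ = [
    "ANOVA_TIME_LEVELS",
    "ANOVA_COND_LEVELS",
    "CellBlock",
    "AnovaResult",
    "z_normalize",
    "gg_epsilon",
    "rm_anova_2way",
    "build_cell_blocks",
    "anova_table",
    "anova_summary",
    "significance_stars",
]

logger = logging.getLogger(__name__)

ANOVA_TIME_LEVELS = ("t3", "t4", "t5", "t6")
ANOVA_COND_LEVELS = ("control", "sleep_deprivation")


def z_normalize(
    table: FeatureTable, samples: Sequence[SampleRecord]
) -> FeatureTable:
    """Per (subject, feature) z-scores over that subject's study samples.

    Both conditions and all timepoints are pooled per subject. A
    (subject, feature) pair with zero standard deviation has its values
    set missing and a warning is logged.
    """
    if table.scale_tag != "log10":
        raise DataError(f"z_normalize expects a log10-scale table, got {table.scale_tag!r}")
    pos = {s: j for j, s in enumerate(table.sample_ids)}
    by_subject: dict[str, list[int]] = {}
    for rec in samples:
        if rec.sample_type == "study" and rec.sample_id in pos:
            by_subject.setdefault(rec.subject_id, []).append(pos[rec.sample_id])  # type: ignore[arg-type]
    study_cols = sorted(j for cols in by_subject.values() for j in cols)
    values = np.full((table.n_features, len(study_cols)), np.nan)
    col_map = {j: k for k, j in enumerate(study_cols)}
    n_degenerate = 0
    for subj, cols in by_subject.items():
        block = table.values[:, cols]
        mean = np.nanmean(block, axis=1, keepdims=True)
        sd = np.nanstd(block, axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (block - mean) / sd
        zero = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
        if zero.any():
            z[zero, :] = np.nan
            n_degenerate += int(zero.sum())
        for k, j in enumerate(cols):
            values[:, col_map[j]] = z[:, k]
    if n_degenerate:
        logger.warning(
            "z_normalize: %d (subject, feature) pairs had zero variance; set missing",
            n_degenerate,
        )
    sample_ids = [table.sample_ids[j] for j in study_cols]
    return FeatureTable(list(table.feature_ids), sample_ids, values, scale_tag="zscore")


@dataclass
class CellBlock:
    """One feature's complete-case array: subjects × time levels × conditions."""

    feature_id: str
    subjects: list
    data: np.ndarray  # shape (n, a, b)
    time_levels: tuple = ANOVA_TIME_LEVELS
    cond_levels: tuple = ANOVA_COND_LEVELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n, a, b = self.data.shape
        if n != len(self.subjects):
            raise DataError("subject axis inconsistent with subject list")
        if (a, b) != (len(self.time_levels), len(self.cond_levels)):
            raise DataError("block shape inconsistent with level definitions")
        if n < 3:
            raise DataError(f"feature {self.feature_id!r}: need >= 3 complete subjects")
        if not np.isfinite(self.data).all():
            raise DataError(
                f"feature {self.feature_id!r}: incomplete cells — drop those "
                "subjects before building the block"
            )


@dataclass
class AnovaResult:
    feature_id: str
    ss: dict
    ss_total: float
    df: dict
    epsilon: dict
    f_stats: dict
    p_gg: dict
    p_uncorrected: dict
    pct_total_variation: dict


def gg_epsilon(scores: np.ndarray) -> float:
    """Box/Greenhouse–Geisser epsilon-hat from a subjects × k score matrix.

    With S the sample covariance of the scores and C an orthonormal
    (k−1) × k contrast basis, M = C S Cᵀ and
    ε = tr(M)² / ((k−1) tr(M²)), clamped to [1/(k−1), 1].
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if k < 2:
        raise DataError("gg_epsilon needs at least 2 within-subject levels")
    if k == 2:
        return 1.0
    S = np.cov(scores, rowvar=False, ddof=1)
    # orthonormal contrast basis: rows of Q orthogonal to the unit vector
    full = np.linalg.qr(
        np.column_stack([np.ones(k) / np.sqrt(k), np.eye(k)[:, : k - 1]])
    )[0]
    C = full[:, 1:].T
    M = C @ S @ C.T
    tr2 = float(np.trace(M @ M))
    if tr2 <= 0.0 or not np.isfinite(tr2):
        return 1.0
    eps = float(np.trace(M)) ** 2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _f_pvalue(ss_num: float, df_num: float, ss_den: float, df_den: float,
              eps: float) -> tuple[float, float, float]:
    """(F, p_gg, p_uncorrected) for one effect; degenerate cases per the
    zero-variance conventions (0/0 → p = 1, x/0 → p = 0)."""
    if ss_den <= 0.0:
        if ss_num <= 0.0:
            return 0.0, 1.0, 1.0
        return float("inf"), 0.0, 0.0
    f = (ss_num / df_num) / (ss_den / df_den)
    p_unc = float(stats.f.sf(f, df_num, df_den))
    p_gg = float(stats.f.sf(f, eps * df_num, eps * df_den))
    return float(f), p_gg, p_unc


def rm_anova_2way(block: CellBlock) -> AnovaResult:
    """Classical within-within decomposition of a balanced block."""
    y = block.data
    n, a, b = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss = {
        "subject": a * b * float(((m_s - grand) ** 2).sum()),
        "time": n * b * float(((m_a - grand) ** 2).sum()),
        "sleep": n * a * float(((m_b - grand) ** 2).sum()),
        "time_x_sleep": n * float(
            ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
        ),
        "time_x_subject": b * float(
            ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
        ),
        "sleep_x_subject": a * float(
            ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
        ),
    }
    ss_total = float(((y - grand) ** 2).sum())
    ss["time_x_sleep_x_subject"] = max(ss_total - sum(ss.values()), 0.0)

    df = {
        "subject": n - 1,
        "time": a - 1,
        "sleep": b - 1,
        "time_x_sleep": (a - 1) * (b - 1),
        "time_x_subject": (a - 1) * (n - 1),
        "sleep_x_subject": (b - 1) * (n - 1),
        "time_x_sleep_x_subject": (a - 1) * (b - 1) * (n - 1),
    }

    eps = {
        "time": gg_epsilon(m_sa),
        "sleep": 1.0,
        # interaction: per-subject condition-difference scores across time
        "time_x_sleep": gg_epsilon(y[:, :, 1] - y[:, :, 0]),
    }

    f_stats: dict = {}
    p_gg: dict = {}
    p_unc: dict = {}
    for effect, err in (
        ("time", "time_x_subject"),
        ("sleep", "sleep_x_subject"),
        ("time_x_sleep", "time_x_sleep_x_subject"),
    ):
        f, pg, pu = _f_pvalue(ss[effect], df[effect], ss[err], df[err], eps[effect])
        f_stats[effect] = f
        p_gg[effect] = pg
        p_unc[effect] = pu

    if ss_total > 0:
        pct = {k: 100.0 * ss[k] / ss_total for k in ("time", "sleep", "subject")}
    else:
        pct = {k: 0.0 for k in ("time", "sleep", "subject")}

    return AnovaResult(
        feature_id=block.feature_id,
        ss=ss,
        ss_total=ss_total,
        df=df,
        epsilon=eps,
        f_stats=f_stats,
        p_gg=p_gg,
        p_uncorrected=p_unc,
        pct_total_variation=pct,
    )


def build_cell_blocks(
    table: FeatureTable, samples: Sequence[SampleRecord]
) -> tuple[list[CellBlock], dict]:
    """Complete-case blocks per feature; subjects with any missing cell in
    the t3–t6 × condition grid are dropped for that feature (counted)."""
    pos = {s: j for j, s in enumerate(table.sample_ids)}
    cell_col: dict[tuple[str, str, str], int] = {}
    subjects = sorted(
        {r.subject_id for r in samples if r.sample_type == "study" and r.sample_id in pos}
    )
    for rec in samples:
        if rec.sample_type == "study" and rec.sample_id in pos:
            cell_col[(rec.subject_id, rec.timepoint, rec.condition)] = pos[rec.sample_id]  # type: ignore[arg-type]

    blocks: list[CellBlock] = []
    dropped: dict = {}
    for i, fid in enumerate(table.feature_ids):
        data = np.full((len(subjects), len(ANOVA_TIME_LEVELS), len(ANOVA_COND_LEVELS)), np.nan)
        for s, subj in enumerate(subjects):
            for ai, tp in enumerate(ANOVA_TIME_LEVELS):
                for bi, cond in enumerate(ANOVA_COND_LEVELS):
                    col = cell_col.get((subj, tp, cond))
                    if col is not None:
                        data[s, ai, bi] = table.values[i, col]
        complete = np.isfinite(data).all(axis=(1, 2))
        n_drop = int((~complete).sum())
        if n_drop:
            dropped[fid] = n_drop
        if complete.sum() < 3:
            raise DataError(
                f"feature {fid!r}: only {int(complete.sum())} complete subjects "
                "for the ANOVA block"
            )
        blocks.append(
            CellBlock(
                feature_id=fid,
                subjects=[subjects[s] for s in np.where(complete)[0]],
                data=data[complete],
            )
        )
    if dropped:
        logger.info(
            "ANOVA blocks: dropped incomplete subjects for %d features", len(dropped)
        )
    return blocks, dropped


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


ANOVA_TABLE_COLUMNS = [
    "feature_id",
    "mode",
    "pct_time",
    "pct_sleep",
    "pct_subject",
    "p_time",
    "p_sleep",
    "p_interaction",
    "eps_time",
    "eps_sleep",
    "eps_interaction",
    "stars_time",
    "stars_sleep",
    "stars_interaction",
    "n_subjects",
]


def anova_table(
    table: FeatureTable, samples: Sequence[SampleRecord]
) -> pd.DataFrame:
    """Per-feature ANOVA rows on the table's scale (log10 or zscore)."""
    if table.scale_tag not in ("log10", "zscore"):
        raise DataError("anova_table expects a log10- or zscore-scale table")
    blocks, _dropped = build_cell_blocks(table, samples)
    rows = []
    for block in blocks:
        res = rm_anova_2way(block)
        rows.append(
            {
                "feature_id": res.feature_id,
                "mode": table.scale_tag,
                "pct_time": res.pct_total_variation["time"],
                "pct_sleep": res.pct_total_variation["sleep"],
                "pct_subject": res.pct_total_variation["subject"],
                "p_time": res.p_gg["time"],
                "p_sleep": res.p_gg["sleep"],
                "p_interaction": res.p_gg["time_x_sleep"],
                "eps_time": res.epsilon["time"],
                "eps_sleep": res.epsilon["sleep"],
                "eps_interaction": res.epsilon["time_x_sleep"],
                "stars_time": significance_stars(res.p_gg["time"]),
                "stars_sleep": significance_stars(res.p_gg["sleep"]),
                "stars_interaction": significance_stars(res.p_gg["time_x_sleep"]),
                "n_subjects": len(block.subjects),
            }
        )
    return pd.DataFrame(rows, columns=ANOVA_TABLE_COLUMNS)


def anova_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median/min/max of the percent-of-total-variation columns."""
    rows = []
    for stat, fn in (("median", np.median), ("min", np.min), ("max", np.max)):
        row = {"statistic": stat}
        for col in ("pct_time", "pct_sleep", "pct_subject"):
            row[col] = float(fn(table[col])) if len(table) else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["statistic", "pct_time", "pct_sleep", "pct_subject"])
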