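import numpy as np
import pandas as pd
import pytest

from sleepmet.preprocess import (
    FilterThresholds,
    compute_feature_qc,
    correct_drift,
    filter_features,
    filter_subjects,
    impute_lod,
    log_transform,
    run_preprocessing,
)
from sleepmet.simulate import SimConfig, generate_dataset
from sleepmet.studydata import (
    ConfigError,
    DataError,
    FeatureTable,
    SampleRecord,
)

NAN = np.nan


def _records(qc=3, dil=0, blank=0, study=0, n_subjects=None):
    """Sequential-run-order metadata: blank(s), QC(s), dilution(s), study."""
    recs = []
    run = 0
    for k in range(blank):
        run += 1
        recs.append(SampleRecord(f"blank{k+1}", "blank", run))
    for k in range(qc):
        run += 1
        recs.append(SampleRecord(f"qc{k+1}", "qc_pool", run))
    fracs = (1.0, 0.5, 0.2, 0.1)
    for k in range(dil):
        run += 1
        recs.append(
            SampleRecord(f"dil{k+1}", "dilution", run, dilution_fraction=fracs[k % 4])
        )
    n_subjects = n_subjects if n_subjects is not None else study
    per = max(1, study // max(n_subjects, 1))
    tps = ("t1", "t2", "t3", "t4", "t5", "t6", "t7")
    idx = 0
    for k in range(study):
        run += 1
        subj = f"s{(k % n_subjects) + 1:02d}"
        # cycle conditions/timepoints so design cells stay unique
        cond = "control" if (k // n_subjects) % 2 == 0 else "sleep_deprivation"
        tp = tps[(k // (2 * n_subjects)) % 7]
        recs.append(
            SampleRecord(f"st{k+1}", "study", run, subject_id=subj,
                         condition=cond, timepoint=tp)
        )
        idx += 1
    return recs


def _table(rows: dict, records, scale="raw"):
    sample_ids = [r.sample_id for r in records]
    values = np.array([rows[f] for f in rows], dtype=float)
    return FeatureTable(list(rows), sample_ids, values, scale)


class TestCorrectDrift:
    def test_constant_qc_trend_is_identity(self):
        recs = _records(qc=4, study=6)
        rows = {"f1": [100.0] * 4 + [5, 10, 15, 20, 25, 30]}
        table = _table(rows, recs)
        corrected, passthrough = correct_drift(table, recs)
        assert passthrough == []
        np.testing.assert_allclose(corrected.values, table.values, rtol=1e-9)

    def test_linear_drift_removed_exactly(self):
        cfg = SimConfig(
            n_features=10, seed=3, technical_sd_qc=0.0, residual_sd=0.0,
            subject_sd=0.0, drift_slope_range=(0.3, 0.3), lod_quantile=0.0,
            class_mix={"null": 1.0},
        )
        table, recs, _ = generate_dataset(cfg)
        corrected, _pt = correct_drift(table, recs)
        qc = [j for j, r in enumerate(recs) if r.sample_type == "qc_pool"]
        v = corrected.values[:, qc]
        assert np.abs(v / v[:, [0]] - 1).max() < 1e-6

    def test_all_missing_qc_feature_passes_through(self):
        recs = _records(qc=3, study=4)
        rows = {
            "f1": [NAN, NAN, NAN, 1, 2, 3, 4],
            "f2": [10, 20, 30, 1, 2, 3, 4],
        }
        table = _table(rows, recs)
        corrected, passthrough = correct_drift(table, recs)
        assert passthrough == ["f1"]
        np.testing.assert_array_equal(corrected.values[0], table.values[0])

    def test_no_qc_samples_is_an_error(self):
        recs = _records(qc=0, study=4)
        table = _table({"f1": [1, 2, 3, 4]}, recs)
        with pytest.raises(DataError, match="skip"):
            correct_drift(table, recs)

    def test_invariant_to_feature_relabeling(self):
        cfg = SimConfig(n_features=8, seed=11, class_mix={"null": 1.0})
        table, recs, _ = generate_dataset(cfg)
        corrected, _ = correct_drift(table, recs)
        perm = [3, 1, 0, 2, 7, 6, 5, 4]
        shuffled = FeatureTable(
            [table.feature_ids[i] for i in perm],
            list(table.sample_ids),
            table.values[perm],
            "raw",
        )
        corr2, _ = correct_drift(shuffled, recs)
        np.testing.assert_allclose(corr2.values, corrected.values[perm], rtol=1e-12)

    def test_preserves_zero_pattern_and_sign(self):
        recs = _records(qc=3, study=4)
        rows = {"f1": [10, 12, 14, 0.0, 5.0, NAN, 7.0]}
        table = _table(rows, recs)
        corrected, _ = correct_drift(table, recs)
        out = corrected.values[0]
        assert out[3] == 0.0
        assert np.isnan(out[5])
        assert (out[[4, 6]] > 0).all()


def _metric_records():
    """blank, 3 QC, 4 dilution, 3 study samples."""
    recs = [SampleRecord("blank1", "blank", 1)]
    recs += [SampleRecord(f"qc{k}", "qc_pool", 1 + k) for k in (1, 2, 3)]
    for k, frac in enumerate((1.0, 0.5, 0.2, 0.1), start=1):
        recs.append(SampleRecord(f"dil{k}", "dilution", 4 + k, dilution_fraction=frac))
    for k, subj in enumerate(("s01", "s02", "s03"), start=1):
        recs.append(
            SampleRecord(f"st{k}", "study", 8 + k, subject_id=subj,
                         condition="control", timepoint="t3")
        )
    return recs


class TestComputeFeatureQc:
    def test_documented_metric_values(self):
        recs = _metric_records()
        rows = {
            "fa": [0.0, 90, 100, 110, 1000, 500, 200, 100, 60, 100, 140],
        }
        table = _table(rows, recs, scale="corrected")
        report = compute_feature_qc(table, recs)
        row = report.iloc[0]
        assert row["rsd_qc_pct"] == pytest.approx(10.0, abs=1e-12)
        assert row["d_ratio_pct"] == pytest.approx(25.0, abs=1e-12)
        assert row["dilution_r2"] == pytest.approx(1.0, abs=1e-12)
        assert not row["blank_detected"]
        assert row["missing_fraction"] == 0.0
        assert row["keep"]

    def test_blank_presence_uses_ratio(self):
        recs = _metric_records()
        rows = {"fa": [6.0, 90, 100, 110, 1000, 500, 200, 100, 60, 100, 140]}
        report = compute_feature_qc(_table(rows, recs, scale="corrected"), recs)
        assert report.iloc[0]["blank_detected"]  # 6 > 5% of mean QC 100

    def test_undefined_metrics_are_nan(self):
        recs = _metric_records()
        rows = {"fa": [0.0, 100, NAN, NAN, 1000, 500, 200, 100, 60, 100, 140]}
        report = compute_feature_qc(_table(rows, recs, scale="corrected"), recs)
        assert np.isnan(report.iloc[0]["rsd_qc_pct"])
        assert not report.iloc[0]["keep"]


def seven_feature_fixture():
    """One clean feature plus six violators, one per quality criterion
    (the sixth violator fails via an undefined RSD under the drop policy)."""
    recs = [SampleRecord("blank1", "blank", 1)]
    recs += [SampleRecord(f"qc{k}", "qc_pool", 1 + k) for k in range(1, 6)]
    for k, frac in enumerate((1.0, 0.5, 0.2, 0.1), start=1):
        recs.append(SampleRecord(f"dil{k}", "dilution", 6 + k, dilution_fraction=frac))
    tps = ("t1", "t2", "t3", "t4", "t5")
    k = 0
    for cond in ("control", "sleep_deprivation"):
        for tp in tps:
            k += 1
            recs.append(
                SampleRecord(f"st{k}", "study", 10 + k, subject_id="s01",
                             condition=cond, timepoint=tp)
            )
    clean_study = [80, 90, 100, 110, 120, 85, 95, 105, 115, 100.0]
    wide_study = [10, 60, 110, 160, 210, 260, 310, 360, 50, 150.0]
    flat_study = [100, 101, 99, 100, 102, 98, 100, 101, 99, 100.0]
    good_qc = [100, 100, 100, 100, 100.0]
    good_dil = [1000, 500, 200, 100.0]
    rows = {
        "clean":       [0.0] + good_qc + good_dil + clean_study,
        "in_blank":    [50.0] + good_qc + good_dil + clean_study,
        "high_rsd":    [0.0] + [50, 75, 100, 125, 150.0] + good_dil + wide_study,
        "bad_dilution": [0.0] + good_qc + [50, 100, 50, 100.0] + clean_study,
        "high_dratio": [0.0] + [90, 95, 100, 105, 110.0] + good_dil + flat_study,
        "too_missing": [0.0] + good_qc + good_dil
                       + [NAN, NAN, NAN, NAN, 100, 110, 90, 100, 105, 95],
        "undef_rsd":   [0.0] + [100, 100, NAN, NAN, NAN] + good_dil + clean_study,
    }
    return recs, _table(rows, recs, scale="corrected")


class TestFilterFeatures:
    def test_exactly_one_kept(self):
        recs, table = seven_feature_fixture()
        report = compute_feature_qc(table, recs)
        kept = filter_features(report)
        assert kept == ["clean"]

    def test_each_violator_fails_its_criterion(self):
        recs, table = seven_feature_fixture()
        report = compute_feature_qc(table, recs).set_index("feature_id")
        assert report.loc["in_blank", "blank_detected"]
        assert report.loc["high_rsd", "rsd_qc_pct"] > 25
        assert report.loc["bad_dilution", "dilution_r2"] < 0.7
        assert report.loc["high_dratio", "d_ratio_pct"] > 50
        assert report.loc["too_missing", "missing_fraction"] > 0.30
        assert np.isnan(report.loc["undef_rsd", "rsd_qc_pct"])

    def test_vacuous_thresholds_keep_everything(self):
        recs, table = seven_feature_fixture()
        report = compute_feature_qc(table, recs)
        thr = FilterThresholds(
            rsd_max_pct=np.inf, r2_min=0.0, d_ratio_max_pct=np.inf,
            missing_max_fraction=1.0, blank_ratio_max=np.inf,
        )
        kept = filter_features(report, thr, policy_undefined="keep")
        assert len(kept) == 7

    def test_boundary_rsd_exactly_25_is_kept(self):
        recs = _metric_records()
        # QC {75,100,125}: sd = 25, mean = 100 → RSD exactly 25%
        rows = {"fa": [0.0, 75, 100, 125, 1000, 500, 200, 100, 10, 150, 290]}
        report = compute_feature_qc(_table(rows, recs, scale="corrected"), recs)
        assert report.iloc[0]["rsd_qc_pct"] == pytest.approx(25.0, abs=1e-12)
        assert filter_features(report) == ["fa"]

    def test_boundary_missing_exactly_30pct_is_kept(self):
        recs, table = seven_feature_fixture()
        vals = dict(zip(table.feature_ids, table.values))
        row = list(vals["clean"])
        for j in (10, 11, 12):  # 3 of 10 study cells
            row[j] = NAN
        table2 = _table({"fb": row}, recs, scale="corrected")
        report = compute_feature_qc(table2, recs)
        assert report.iloc[0]["missing_fraction"] == pytest.approx(0.30)
        assert filter_features(report) == ["fb"]

    def test_deterministic_on_simulator_fixture(self, small_dataset):
        _cfg, table, recs, _ = small_dataset
        corrected, _ = correct_drift(table, recs)
        k1 = filter_features(compute_feature_qc(corrected, recs))
        k2 = filter_features(compute_feature_qc(corrected, recs))
        assert k1 == k2

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigError):
            FilterThresholds(rsd_max_pct=-1).validate()


class TestFilterSubjects:
    def _grid(self, missing_by_subject):
        recs = []
        run = 0
        rows = []
        subjects = sorted(missing_by_subject)
        cols = []
        for subj in subjects:
            for k in range(10):
                run += 1
                cond = "control" if k % 2 == 0 else "sleep_deprivation"
                tp = ("t1", "t2", "t3", "t4", "t5")[k // 2]
                recs.append(
                    SampleRecord(f"{subj}_{k}", "study", run, subject_id=subj,
                                 condition=cond, timepoint=tp)
                )
                cols.append(subj)
        values = np.ones((2, len(cols)))
        for subj, n_missing in missing_by_subject.items():
            idx = [j for j, s in enumerate(cols) if s == subj]
            for j in idx[:n_missing]:
                values[:, j] = NAN
        table = FeatureTable(["f1", "f2"], [r.sample_id for r in recs], values,
                             "corrected")
        return table, recs

    def test_complete_subject_kept_half_missing_dropped(self):
        table, recs = self._grid({"s01": 0, "s02": 5, "s03": 0, "s04": 0})
        kept = filter_subjects(table, recs)
        assert kept == ["s01", "s03", "s04"]

    def test_boundary_exactly_30pct_kept(self):
        table, recs = self._grid({"s01": 3, "s02": 0, "s03": 0, "s04": 0})
        kept = filter_subjects(table, recs)
        assert "s01" in kept  # strictly-more-than rule

    def test_fewer_than_three_subjects_is_error(self):
        table, recs = self._grid({"s01": 10, "s02": 10, "s03": 0, "s04": 0})
        with pytest.raises(DataError, match="3"):
            filter_subjects(table, recs)


class TestImputeLod:
    def test_fifth_of_minimum(self):
        recs = [
            SampleRecord(f"st{k}", "study", k, subject_id=f"s{k:02d}",
                         condition="control", timepoint="t3")
            for k in (1, 2, 3)
        ]
        table = _table({"f1": [10.0, NAN, 50.0]}, recs)
        out, n = impute_lod(table, recs)
        np.testing.assert_allclose(out.values[0], [10.0, 2.0, 50.0])
        assert n == 1

    def test_no_missing_is_identity(self):
        recs = [
            SampleRecord(f"st{k}", "study", k, subject_id=f"s{k:02d}",
                         condition="control", timepoint="t3")
            for k in (1, 2, 3)
        ]
        table = _table({"f1": [10.0, 20.0, 50.0]}, recs)
        out, n = impute_lod(table, recs)
        assert n == 0
        np.testing.assert_array_equal(out.values, table.values)

    def test_zero_values_also_imputed(self):
        recs = [
            SampleRecord(f"st{k}", "study", k, subject_id=f"s{k:02d}",
                         condition="control", timepoint="t3")
            for k in (1, 2, 3)
        ]
        table = _table({"f1": [0.0, 10.0, 50.0]}, recs)
        out, n = impute_lod(table, recs)
        assert out.values[0, 0] == pytest.approx(2.0)
        assert n == 1

    def test_no_positive_value_is_error(self):
        recs = [
            SampleRecord(f"st{k}", "study", k, subject_id=f"s{k:02d}",
                         condition="control", timepoint="t3")
            for k in (1, 2, 3)
        ]
        table = _table({"fbad": [0.0, NAN, 0.0]}, recs)
        with pytest.raises(DataError, match="fbad"):
            impute_lod(table, recs)

    def test_replacement_fraction_order_of_magnitude(self):
        fracs = []
        for seed in range(10):
            cfg = SimConfig(n_features=80, seed=seed, class_mix={"null": 1.0},
                            drift_slope_range=(0.0, 0.0))
            table, recs, _ = generate_dataset(cfg)
            n_study = sum(1 for r in recs if r.sample_type == "study")
            _, n = impute_lod(table, recs)
            fracs.append(n / (table.n_features * n_study))
        assert 0.03 <= float(np.mean(fracs)) <= 0.09


class TestLogTransform:
    def _study(self, vals):
        recs = [
            SampleRecord(f"st{k}", "study", k, subject_id=f"s{k:02d}",
                         condition="control", timepoint="t3")
            for k in range(1, len(vals) + 1)
        ]
        return _table({"f1": vals}, recs), recs

    def test_log10_values(self):
        table, recs = self._study([100.0, 1.0, 10.0])
        out = log_transform(table, recs)
        np.testing.assert_allclose(out.values[0], [2.0, 0.0, 1.0])
        assert out.scale_tag == "log10"

    def test_nonpositive_names_cell(self):
        table, recs = self._study([100.0, 0.0, 10.0])
        with pytest.raises(DataError, match="f1.*st2"):
            log_transform(table, recs)

    def test_roundtrip_inverse(self):
        table, recs = self._study([3.7, 12.9, 4500.0])
        out = log_transform(table, recs)
        np.testing.assert_allclose(10.0 ** out.values, table.values, rtol=1e-12)

    def test_blanks_dropped(self):
        recs = [SampleRecord("blank1", "blank", 1)] + [
            SampleRecord(f"st{k}", "study", 1 + k, subject_id=f"s{k:02d}",
                         condition="control", timepoint="t3")
            for k in (1, 2)
        ]
        table = _table({"f1": [0.0, 10.0, 100.0]}, recs)
        out = log_transform(table, recs)
        assert out.sample_ids == ["st1", "st2"]


class TestPipeline:
    def test_order_and_counts(self, small_dataset):
        _cfg, table, recs, _ = small_dataset
        pre = run_preprocessing(table, recs)
        assert pre.table_log10.scale_tag == "log10"
        assert set(pre.table_log10.feature_ids) <= set(pre.kept_features)
        assert len(pre.kept_subjects) >= 3
        assert pre.n_imputed >= 0
        # log table contains no blank injections and no missing study cells
        study_ids = {r.sample_id for r in recs if r.sample_type == "study"}
        cols = [j for j, s in enumerate(pre.table_log10.sample_ids) if s in study_ids]
        assert np.isfinite(pre.table_log10.values[:, cols]).all()

    def test_post_correction_rsd_improves(self, small_dataset):
        _cfg, table, recs, _ = small_dataset
        corrected, _ = correct_drift(table, recs)
        qc = [j for j, r in enumerate(recs) if r.sample_type == "qc_pool"]

        def rsd(t):
            v = t.values[:, qc]
            return 100 * np.nanstd(v, axis=1, ddof=1) / np.nanmean(v, axis=1)

        frac = float(np.mean(rsd(corrected) <= rsd(table)))
        assert frac >= 0.95
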