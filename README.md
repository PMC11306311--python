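# sleepmet

Preprocessing and within-subject statistics for metabolomics feature
tables from crossover sleep-deprivation studies, together with a
synthetic-data generator that emulates the full study design (13
subjects × 2 conditions × 7 sampling timepoints, QC pools every 5
injections, process blank, bracketing dilution series, run-order drift,
LOD censoring).

The pipeline stages, in fixed order:

1. **Drift correction** (`preprocess.correct_drift`) — per-feature,
   per-batch locally weighted regression of QC-pool abundances against
   run order (window = 8 QC points), interpolated to every injection and
   applied as a multiplicative rescaling to the batch QC median.
2. **Feature quality filter** (`preprocess.compute_feature_qc`,
   `filter_features`) — a feature is removed if it is present in the
   process blank, QC RSD > 25 %, dilution-series r² < 0.7,
   D-ratio > 50 %, or more than 30 % of study values are missing/zero.
3. **Subject filter** (`filter_subjects`) — subjects with more than 30 %
   missing-or-zero values are excluded.
4. **Imputation** (`impute_lod`) — missing/zero study values are replaced
   by one fifth of the feature's lowest detected value.
5. **log10 transform** (`log_transform`), and optionally subject-wise
   **z-score normalization** (`rmstats.z_normalize`).
6. **Repeated-measures two-way ANOVA** (`rmstats`) — time (t3–t6) ×
   sleep condition, both within-subject, Greenhouse–Geisser-corrected
   p-values and percent-of-total-variation per effect, in both log10 and
   z-score modes.
7. **Per-timepoint paired t-tests and profile classification**
   (`sleepclass`) — deprivation vs. control at each of t1–t7
   (default alpha 0.01), then each feature is classified as
   `non_robust` (significant before the experimental night),
   `non_adaptive` (still significant after the recovery night),
   `sleep_linear` (significant at all of t3–t6), `sleep_rhythmic`
   (significant at some of t3–t6), or `unaffected`.

## CLI

```sh
# full synthetic-study run: simulate + all pipeline stages + manifest
sleepmet run-all --seed 5 --out-dir out/

# individual stages
sleepmet simulate --seed 3 --n-features 500 --out-stem out/sim
sleepmet correct  --features out/sim_features.csv --samples out/sim_samples.csv --out out/corrected.csv
sleepmet qc       --features out/corrected.csv --samples out/sim_samples.csv --out out/qc.csv
sleepmet filter   --features out/corrected.csv --samples out/sim_samples.csv \
                  --qc-report out/qc.csv --out out/log10.csv
sleepmet analyze  --features out/log10.csv --samples out/sim_samples.csv --out-stem out/res
sleepmet classify --features out/log10.csv --samples out/sim_samples.csv --alpha 0.01 \
                  --out-stem out/res
```

`run-all` accepts a YAML config with `simulate`, `thresholds` and
`pipeline` sections; every artifact is a CSV plus a `manifest.json`
recording the seed, configuration and per-stage counts. Identical
config + seed reproduces byte-identical artifacts. Exit codes: 0 ok,
2 config error, 3 data error, 4 stage failure.

All tables are plain CSV. Sample metadata columns: `sample_id,
sample_type, subject_id, condition, timepoint, run_order, batch,
dilution_fraction, clock_hour`. Feature tables are features × samples
with a leading `feature_id` column; empty cells are missing values.

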