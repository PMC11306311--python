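import numpy as np
import pytest

from sleepmet.simulate import SimConfig, generate_dataset
from sleepmet.studydata import (
    CONDITIONS,
    TIMEPOINTS,
    FeatureTable,
    SampleRecord,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Default-parameter simulation at a size the whole suite can share."""
    cfg = SimConfig(n_features=60, seed=7)
    table, records, truth = generate_dataset(cfg)
    return cfg, table, records, truth


def build_study_grid(y, scale_tag="log10"):
    """Construct a study-only FeatureTable plus records from an array
    y[feature, subject, condition, timepoint] (NaN = missing)."""
    y = np.asarray(y, dtype=float)
    nf, ns, nc, nt = y.shape
    assert nc == 2 and nt == len(TIMEPOINTS)
    records = []
    values = np.empty((nf, ns * nc * nt))
    sample_ids = []
    run = 0
    for s in range(ns):
        for c, cond in enumerate(CONDITIONS):
            for t, tp in enumerate(TIMEPOINTS):
                run += 1
                sid = f"s{s + 1:02d}_{'ctl' if c == 0 else 'dep'}_{tp}"
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        sample_type="study",
                        run_order=run,
                        subject_id=f"s{s + 1:02d}",
                        condition=cond,
                        timepoint=tp,
                    )
                )
                sample_ids.append(sid)
                values[:, run - 1] = y[:, s, c, t]
    feature_ids = [f"F{k + 1:03d}" for k in range(nf)]
    table = FeatureTable(feature_ids, sample_ids, values, scale_tag=scale_tag)
    return table, records


@pytest.fixture
def study_grid_builder():
    return build_study_grid
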