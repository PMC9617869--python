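"""Shared fixtures.

The default-condition cohort (20 patients + 20 controls, 20 nodes, 190
volumes) and its pipeline stages are computed once per session and shared
across the recovery and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import dynconn as dc

COHORT_SEED = 0


@pytest.fixture(scope="session")
def default_cohort():
    cfg = dc.default_config(seed=COHORT_SEED)
    subjects, gt = dc.simulate_cohort(cfg)
    return cfg, subjects, gt


@pytest.fixture(scope="session")
def cohort_dfc(default_cohort):
    _, subjects, _ = default_cohort
    params = dc.WindowParams(width_tr=22, step_tr=1)
    return {ts.subject_id: dc.sliding_window_fc(ts, params) for ts in subjects}


@pytest.fixture(scope="session")
def pooled_windows(cohort_dfc):
    return dc.stack_window_vectors(cohort_dfc.values())


@pytest.fixture(scope="session")
def state_model(pooled_windows):
    X, sids = pooled_windows
    return dc.fit_states(X, k=2, seed=COHORT_SEED, subject_ids=sids)


@pytest.fixture(scope="session")
def cohort_topo(cohort_dfc):
    return {
        sid: dc.subject_topo_dynamics(series)
        for sid, series in cohort_dfc.items()
    }


@pytest.fixture(scope="session")
def feature_table(default_cohort, state_model, cohort_topo):
    _, subjects, _ = default_cohort
    metrics = {
        ts.subject_id: dc.state_metrics(
            state_model.labels_for(ts.subject_id), state_model.k
        )
        for ts in subjects
    }
    groups = {ts.subject_id: ts.group for ts in subjects}
    return dc.build_feature_table(metrics, cohort_topo, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
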