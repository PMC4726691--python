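import numpy as np
import pandas as pd
import pytest

from ventdose import TruthParams, make_analysis_table, simulate_study

STUDY_SEED = 101  # fixed synthetic-study realization shared across tests


def build_table(seed, n_subjects=15, truth=None, timebase="30"):
    cohort, sessions = simulate_study(n_subjects, seed, truth)
    table = make_analysis_table(cohort, sessions, timebase)
    return cohort, sessions, table


@pytest.fixture(scope="session")
def study():
    """One 15-subject synthetic treadmill study at the default truth."""
    cohort, sessions, table = build_table(STUDY_SEED)
    return dict(cohort=cohort, sessions=sessions, table=table, truth=TruthParams())


@pytest.fixture(scope="session")
def noiseless_study():
    """Same design with tau = sigma = 0, averaged on the breath time base."""
    truth = TruthParams(tau=0.0, sigma=0.0)
    cohort, sessions, table = build_table(7, n_subjects=5, truth=truth, timebase="ib")
    return dict(cohort=cohort, sessions=sessions, table=table, truth=truth)


def toy_lmm_dataset(seed, n_subjects=3, n_per=4, beta=(1.0, 0.5), tau=0.7, sigma=0.4):
    """Tiny random-intercept dataset for oracle comparisons."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        b = rng.normal(0, tau)
        x = rng.normal(0, 1, n_per)
        y = beta[0] + beta[1] * x + b + rng.normal(0, sigma, n_per)
        for xi, yi in zip(x, y):
            rows.append(dict(subject_id=f"s{i}", x=xi, y=yi))
    return pd.DataFrame(rows)
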