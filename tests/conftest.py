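import numpy as np
import pandas as pd
import pytest

from actvar.series import ActivityTimeSeries, minute_grid


def make_series(values, start="2020-04-06", states=None,
                participant_id="T0") -> ActivityTimeSeries:
    """Build an ActivityTimeSeries from a flat array of minute MET values.

    ``start`` defaults to a Monday so day-of-week arithmetic is easy to
    reason about in tests.  ``states`` defaults to all-awake.
    """
    values = np.asarray(values, dtype=float)
    n_days = int(np.ceil(len(values) / 1440))
    grid = minute_grid(pd.Timestamp(start), n_days)[: len(values)]
    if states is None:
        states = np.full(len(values), "awake", dtype=object)
    df = pd.DataFrame({"met": values,
                       "state": pd.Categorical(states,
                                               categories=["awake", "asleep"])},
                      index=grid)
    return ActivityTimeSeries(participant_id, df)


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants x 8 weeks, no missingness: shared read-only cohort."""
    from actvar.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_participants=12, days=56, seed=7, missingness=[])
    return generate_cohort(spec)
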