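import numpy as np
import pytest

import hubnet as h


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 3+3-subject, 20-region cohort with default planted effects."""
    spec = h.CohortSpec(n_subjects_per_group=3, n_regions=20, n_volumes=120, seed=11)
    return spec, h.simulate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def raw_timeseries(subject):
    """Wrap a synthetic subject's emitted series without conditioning."""
    return h.RegionalTimeSeries(
        subject_id=subject.subject_id,
        data=subject.timeseries,
        region_labels=subject.region_labels,
        tr_seconds=subject.tr_seconds,
    )
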