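import numpy as np
import pytest

from circphen import synthetic_cohort as sc
from circphen.synthetic_cohort import ActivitySeries


def make_series(counts, epoch_minutes=60, start_hours=0.0, rest_intervals=None):
    counts = np.asarray(counts, dtype=float)
    epoch_h = epoch_minutes / 60.0
    starts = start_hours + np.arange(counts.size) * epoch_h
    return ActivitySeries("T", starts, epoch_minutes, counts, rest_intervals or [])


@pytest.fixture(scope="session")
def default_cohort_40():
    """The study-emulating default cohort: 40 subjects, morning-leaning mix."""
    return sc.generate_cohort(sc.default_config(seed=1))


@pytest.fixture(scope="session")
def default_run_200():
    """A full validation run on 200 subjects under default generative conditions."""
    from circphen import pipeline as pl
    return pl.run_validation(sc.default_config(n_subjects=200), seed=42)
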