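import numpy as np
import pandas as pd
import pytest

from gluconet import (CGMGenParams, CGMSeries, SampleConfig, build_samples,
                      fill_gaps, generate_cgm_cohort, standardize)


@pytest.fixture(scope="session")
def gen_params() -> CGMGenParams:
    """Small cohort settings shared across tests (1 week, defaults otherwise)."""
    return CGMGenParams(days=7, seed=123)


@pytest.fixture(scope="session")
def small_cohort(gen_params):
    return generate_cgm_cohort(gen_params, 3)


@pytest.fixture(scope="session")
def filled_series(small_cohort):
    return fill_gaps(small_cohort[0])


@pytest.fixture(scope="session")
def standardized_samples(filled_series):
    """A standardized (train, validation) pair from one synthetic patient."""
    samples = build_samples(filled_series, SampleConfig.two_point(5))
    n = len(samples)
    train = samples.subset(np.arange(0, int(0.8 * n)))
    val = samples.subset(np.arange(int(0.8 * n), n))
    train_s, (val_s,), params = standardize(train, [val])
    return train_s, val_s, params


def make_series(values, mask=None, interval=5, patient="T01") -> CGMSeries:
    """Small hand-built series helper used across test modules."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = ~np.isnan(values)
    return CGMSeries(
        patient_id=patient,
        start_time=pd.Timestamp("2022-01-01 00:00:00"),
        sampling_interval=interval,
        values=values,
        observed_mask=np.asarray(mask, dtype=bool),
    )
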