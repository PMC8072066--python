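import numpy as np
import pandas as pd
import pytest

import labelflux as lf


@pytest.fixture(scope="session")
def truth():
    """Reference kinetics and initial sizes used across tests."""
    return lf.default_truth()


@pytest.fixture(scope="session")
def designs():
    return lf.preset_designs()


def preprocess(tables, offsets=2.0):
    """Standard pipeline: validate, time-zero shift, 40-week window, pooling,
    pooled-variance SEMs, bin-level HSC normalization."""
    df = pd.concat(tables, ignore_index=True)
    df = lf.validate_observations(df)
    df = lf.adjust_time_zero(df, offsets)
    df = lf.restrict_window(df)
    pooled = lf.pooled_variance_sem(lf.pool_timepoints(df))
    return lf.normalize_pooled_to_hsc(pooled)


@pytest.fixture(scope="session")
def joint_fit(truth, designs):
    """One noisy two-dataset cohort fitted jointly; reused by several tests."""
    rates, init = truth
    tabs = lf.generate_multi_dataset(
        rates, init, [designs["tie2-like"], designs["fgd5-like"]], seed=42)
    pooled = preprocess(tabs)
    fds = lf.fit_datasets_from_pooled(pooled)
    spec = lf.make_fitspec([d.dataset_id for d in fds])
    fit = lf.fit_joint(fds, spec, n_starts=8, seed=1)
    return fit


def random_distinct_kappa_instance(rng, k=4):
    """Random cascade instance with pairwise-distinct inverse residence times."""
    while True:
        kappa = rng.uniform(0.005, 0.8, size=k)
        if np.min(np.diff(np.sort(kappa))) > 1e-3:
            break
    alpha = rng.uniform(0.01, 0.5, size=k)
    n0 = rng.uniform(10.0, 5000.0, size=k)
    return lf.KineticRates.from_kappa(alpha, kappa), lf.InitialState(n0=n0)
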