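import numpy as np
import pytest

import neurodyn as nd


@pytest.fixture(scope="session")
def lorenz_x():
    """x-component of a standard Lorenz trajectory (dt=0.01, transient cut)."""
    rec = nd.generate_system(nd.SystemSpec("lorenz", n_samples=5000,
                                           dt_or_fs=0.01))
    return rec.data[0]


@pytest.fixture(scope="session")
def sine_2000():
    """Noise-free 10 Hz sine sampled at 250 Hz for 8 s."""
    t = np.arange(2000) / 250.0
    return np.sin(2 * np.pi * 10 * t)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A very small synthetic cohort for plumbing tests (not for recovery)."""
    spec = nd.SyntheticCohortSpec(n_subjects=6, n_channels=3, fs=64.0,
                                  duration=16.0, seed=7)
    recs, cohort = nd.generate_cohort(spec)
    return recs, cohort


@pytest.fixture(scope="session")
def tiny_feature_tables(tiny_cohort):
    recs, cohort = tiny_cohort
    cfg = nd.FeatureConfig(rqa_max_points=200)
    tables = {r.meta["subject_id"]: nd.extract_features(r, cfg) for r in recs}
    return tables, cohort
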