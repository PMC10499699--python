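"""Shared fixtures: the worked-example miniature and one full calibration
of the default synthetic bundle (session-scoped; several end-to-end tests
read different aspects of the same calibrated model)."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ibdl import (CalibrationSettings, SimulationConfig, calibrate,
                  make_worked_example, score, simulate_dataset)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: master seed of the shared end-to-end bundle
BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def calibrated_bundle():
    """Default 30-lake synthetic survey, calibrated and scored.

    n_perm = n_boot = 100 keeps the full 11-variable calibration tractable
    while leaving the permutation/bootstrap screens meaningful.
    """
    ds = simulate_dataset(SimulationConfig(seed=BUNDLE_SEED))
    st = CalibrationSettings(seed=BUNDLE_SEED, n_perm=100, n_boot=100)
    res = calibrate(ds.counts, ds.samples, ds.lakes, ds.env, st)
    sc = score(res.model, ds.counts, ds.samples, ds.lakes)
    return ds, res, sc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
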