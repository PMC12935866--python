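import numpy as np
import pytest

import gaittube as gt


@pytest.fixture(scope="session")
def control_trial():
    """One control-preset trial, 90 strides."""
    return gt.generate_trial(gt.control_profile(), n_strides=90, seed=11)


@pytest.fixture(scope="session")
def control_strides(control_trial):
    return gt.strides_from_trial(control_trial.markers, control_trial.vgrf)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, n=3, scale=10.0):
    A = rng.normal(size=(n, n)) * scale
    return A @ A.T + 1e-6 * np.eye(n)


def random_strides(rng, S=40, T=101, sd=(10.0, 10.0, 10.0)):
    values = rng.normal(size=(S, T, 3)) * np.asarray(sd)
    return gt.StrideSet(values=values, stride_times=np.arange(S + 1, dtype=float))
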