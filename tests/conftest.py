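"""Shared fixtures: a small synthetic study bundle and helpers."""

import numpy as np
import pandas as pd
import pytest

from terrapath import studyio, synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SynthConfig(n_individuals=3, days=4, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    return synth.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    studyio.write_study(small_study, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_burst(samples, rate=10.0, individual="T01", ts="2015-06-01 08:00",
               calibration=None):
    from terrapath.accel import AccBurst

    return AccBurst(
        individual=individual,
        timestamp=pd.Timestamp(ts),
        samples=np.asarray(samples, dtype=float),
        rate=rate,
        calibration=calibration,
    )
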