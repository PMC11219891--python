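import warnings

import numpy as np
import pytest

from ecgkit import generate_record, make_rhythm


@pytest.fixture(autouse=True)
def _quiet_comb_warning(caplog):
    # the fs=360 / 50 Hz comb-zero mismatch is expected and logged; keep
    # test output readable
    import logging

    logging.getLogger("ecgkit.filters").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_record():
    """30 s noise-free two-class record at 360 Hz."""
    rhythm = make_rhythm(30.0, mean_rr_s=0.8, ectopic_rate=0.15, seed=7)
    return generate_record(30.0, 360.0, rhythm, seed=7)


def suppress_user_warnings():
    return warnings.catch_warnings()
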