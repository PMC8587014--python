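import warnings

import numpy as np
import pytest

from neurosw.pipeline import scaled_study_config, sw_table_for_cohorts


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    """Silence the informational skipped-bin warnings in bulk runs."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="band .*skipped.*non-positive denominator"
        )
        yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def contrast_sw_table():
    """One scaled planted-contrast study run, shared across tests."""
    cfg = scaled_study_config(seed=42)
    sw, _ = sw_table_for_cohorts(cfg)
    return sw
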