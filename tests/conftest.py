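import numpy as np
import pytest

from ptesleep import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def fast_cohort_config(**overrides) -> synth.CohortConfig:
    """Small, spike-dense cohort so event clustering has material to work
    with on minutes-long records."""
    defaults = dict(
        n_per_arm={"NC": 2, "sham": 2, "CCI": 2},
        hours=0.2,
        fs=256.0,
        seed=7,
        arm_sharp_rate_per_h={"NC": 0.0, "sham": 60.0, "CCI": 150.0},
        background_spike_rate_per_h=60.0,
        seizure_prob={"NC": 0.0, "sham": 0.0, "CCI": 0.0},
    )
    defaults.update(overrides)
    return synth.CohortConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    cfg = fast_cohort_config()
    synth.write_fixture_cohort(cfg, out)
    return out
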