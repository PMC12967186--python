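import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from medmr import HarmonizedSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_hs(beta_x, se_x, beta_y, se_y, snp_ids=None, **kw) -> HarmonizedSet:
    """Build a HarmonizedSet from plain sequences (test helper)."""
    beta_x = np.asarray(beta_x, dtype=float)
    k = len(beta_x)
    if snp_ids is None:
        snp_ids = np.array([f"rs{i + 1}" for i in range(k)], dtype=object)
    return HarmonizedSet(
        exposure_id=kw.pop("exposure_id", "X"),
        outcome_id=kw.pop("outcome_id", "Y"),
        snp_ids=np.asarray(snp_ids, dtype=object),
        beta_x=beta_x,
        se_x=np.asarray(se_x, dtype=float),
        beta_y=np.asarray(beta_y, dtype=float),
        se_y=np.asarray(se_y, dtype=float),
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def homogeneous_hs(rng):
    """20 strong instruments with a common true ratio of 0.3 and small noise."""
    k = 20
    beta_x = rng.uniform(0.1, 0.4, k) * rng.choice([-1, 1], k)
    se_x = np.full(k, 0.01)
    se_y = rng.uniform(0.01, 0.02, k)
    beta_y = 0.3 * beta_x + rng.normal(0, se_y)
    return make_hs(beta_x, se_x, beta_y, se_y)
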