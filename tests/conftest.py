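import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def desk_field_config():
    """Small field images used wherever a test needs to train something."""
    from weedseg import FieldConfig

    return FieldConfig(
        height=48,
        width=64,
        n_crops=2,
        crop_radius_range=(8, 14),
        weed_density=4.0,
        weed_radius_range=(3, 6),
        row_jitter=4.0,
        seed=0,
    )


@pytest.fixture
def desk_pairs(desk_field_config):
    """20 deterministic image/mask pairs at desk scale."""
    from weedseg import generate_field

    return [
        generate_field(desk_field_config, np.random.default_rng([0, i]))
        for i in range(20)
    ]


@pytest.fixture
def tiny_stationary():
    """Smallest reasonable stationary config for training smoke tests."""
    from weedseg import StationaryConfig

    return StationaryConfig(alpha=1.0, base_widths=(4, 8, 16, 32))
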