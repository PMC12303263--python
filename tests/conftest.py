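import numpy as np
import pandas as pd
import pytest

from vocalmod import scales, synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Default 24-speaker synthetic study, volumes on a small grid."""
    cfg = synthetic.SimulationConfig(seed=42, grid_shape=(16, 16, 16), beta_map_gain=6.0)
    return synthetic.simulate(cfg, include_volumes=True)


@pytest.fixture(scope="session")
def small_profiles(small_study):
    return scales.score_profiles(small_study.items, small_study.speakers)


def two_listener_records(intelligent_scale=(4, 4, 7)):
    """Hand-built speaker block: likeable scale (7,1,4), hostile (1,7,4)
    across the (likeable, hostile, intelligent) recordings, two listeners."""
    rows = []
    per_scale = {
        "likeable": {"likeable": 7, "hostile": 1, "intelligent": 4},
        "hostile": {"likeable": 1, "hostile": 7, "intelligent": 4},
        "intelligent": dict(
            zip(("likeable", "hostile", "intelligent"), intelligent_scale)
        ),
    }
    for listener in (0, 1):
        for scale, by_cond in per_scale.items():
            for cond, rating in by_cond.items():
                rows.append(
                    {
                        "listener_id": listener,
                        "speaker_id": 0,
                        "condition": cond,
                        "scale": scale,
                        "rating": rating,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
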