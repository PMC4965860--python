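import numpy as np
import pytest
from hypothesis import settings

import teaspec as t

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from teaspec.synthetic_data import config_from_dict, config_to_dict


def small_synthetic_config(seed: int = 11) -> t.SyntheticConfig:
    """Reduced study design: same 13 levels and noise model, coarse grid
    (360 points over the full range) and 4/3 replicates per level."""
    cfg = t.default_config(seed)
    d = config_to_dict(cfg)
    d["raw_grid"] = (400.0, 4000.0, 360)
    cal = set(cfg.design.calibration_levels)
    d["design"]["replicates_per_level"] = tuple(
        4 if lv in cal else 3 for lv in cfg.design.levels
    )
    return config_from_dict(d)


@pytest.fixture
def small_config() -> t.SyntheticConfig:
    return small_synthetic_config()


@pytest.fixture
def small_data(small_config) -> t.SpectrumSet:
    # 360 -> 300 variables after edge trimming
    return t.trim(t.simulate_dataset(small_config), 30, 30)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
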