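import numpy as np
import pytest

from vifstretch import synthetic as syn


@pytest.fixture(scope="session")
def bead_series():
    """Default 11-step bead stack with truth table (50 beads)."""
    cfg = syn.StretchConfig(seed=11)
    stack, truth = syn.make_bead_series(cfg, n_beads=50)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def small_filament_series():
    """Small decoupled-mode filament series for tracing tests."""
    cfg = syn.StretchConfig(seed=4, eps_yy_max=0.341, eps_xx_max=-0.123)
    stack, truths, lengths = syn.make_filament_series(
        cfg, n_filaments=10, kappa=0.16, shape=(600, 600))
    return cfg, stack, truths, lengths


@pytest.fixture(scope="session")
def texture():
    return syn.texture_image((192, 192), seed=2)
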