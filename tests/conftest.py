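import numpy as np
import pytest

from colonyscreen import FORMATS, SyntheticScreenConfig, render_plate_image, simulate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(20130515)


@pytest.fixture
def screen_96():
    """One deterministic synthetic 96-format screen (truth, control, experiment)."""
    config = SyntheticScreenConfig(format=FORMATS[96], seed=11)
    return simulate_screen(config)


@pytest.fixture
def rendered_384(rng):
    """Noiseless rendered 384 plate with pixel-exact ground truth."""
    fmt = FORMATS[384]
    sizes = rng.uniform(60, 150, fmt.physical_shape)
    image, truth = render_plate_image(sizes, fmt, spacing=16)
    return fmt, sizes, image, truth
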