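import math

import numpy as np
import pytest

from twodsil import (
    ArcSpec,
    EndstoppedConfig,
    FilterBankConfig,
    ModelConfig,
    complex_responses,
    render_arc,
    simple_responses,
)


@pytest.fixture(scope="session")
def small_bank():
    """Two-scale, four-orientation bank: fast but structurally complete
    (4 orientations keep the 45-degree sign-cell flanks addressable)."""
    return FilterBankConfig(
        orientations=tuple(math.radians(45 * k) for k in range(4)),
        sizes=(40, 120),
        aspect_ratios=(0.7, 3.0),
    )


@pytest.fixture(scope="session")
def small_es():
    return EndstoppedConfig(
        flank_gains=(1.5, 3.0),
        sign_displacement_fractions=(0.2, 0.4),
    )


@pytest.fixture(scope="session")
def small_config(small_bank, small_es):
    return ModelConfig(bank=small_bank, endstopped=small_es)


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def arc_stacks(small_bank):
    """Simple and complex stacks for a mid-curvature arc, shared across tests."""
    img = render_arc(ArcSpec(radius=60), antialias=True)
    simple = simple_responses(img, small_bank)
    cx = complex_responses(simple)
    return img, simple, cx
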