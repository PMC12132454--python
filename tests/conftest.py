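import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make wf_oracle importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from optimshift import PointMassEffects, Scenario, TraitScale


@pytest.fixture
def scale_5000():
    return TraitScale(5000)


@pytest.fixture
def scale_1000():
    return TraitScale(1000)


@pytest.fixture
def fig3_scenario(scale_5000):
    """Single large-effect allele setup: a^2=200, sigma^2=40."""
    return Scenario(
        Lambda=50.0, sigma2=40.0, twoNU=0.0,
        effect_dist=PointMassEffects(200.0), scale=scale_5000,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
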