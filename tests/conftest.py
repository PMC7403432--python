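import numpy as np
import pytest
from hypothesis import settings

from glycomn import build_default_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_profile(panel, rng, sample_id="s"):
    """A valid random profile over the panel (sums to exactly 100)."""
    from glycomn import GlycomeProfile

    w = rng.dirichlet(np.ones(len(panel))) * 100.0
    ab = dict(zip(panel.short_names, w))
    top = max(ab, key=ab.get)
    ab[top] += 100.0 - sum(ab.values())
    return GlycomeProfile(sample_id=sample_id, abundance=ab)
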