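import numpy as np
import pytest

from ldafold.structures import CaTrace
from ldafold.synthetic import SyntheticSpec, make_template_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def random_trace(rng):
    def make(n=10, scale=5.0, label="random"):
        return CaTrace(rng.normal(0, scale, (n, 3)), label=label)
    return make


@pytest.fixture(scope="session")
def small_ensemble():
    """A small planted-class ensemble reused across read-only tests."""
    spec = SyntheticSpec(residue_count=30, n_classes=3, templates_per_class=8, seed=11)
    return make_template_ensemble(spec)
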