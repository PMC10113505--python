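import numpy as np
import pytest

from sparrowtune.fixtures import FixtureSpec, generate_image_set


@pytest.fixture(scope="session")
def three_class_set():
    """Small separable 3-class image set, 32x32."""
    spec = FixtureSpec({"a": 20, "b": 20, "c": 20}, image_size=32,
                       signal_strength=1.0, noise_sd=8.0, seed=11)
    return generate_image_set(spec)


@pytest.fixture(scope="session")
def four_class_set():
    """Imbalanced 4-class fixture shaped like the CT triage problem."""
    spec = FixtureSpec.four_class(counts=(12, 18, 8, 14), image_size=32, seed=5)
    return generate_image_set(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
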