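import numpy as np
import pytest

from mmpso_s.fixtures import FixtureSpec, make_nuclei_image


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def nuclei_fixture():
    """One deterministic synthetic H&E-like image with ground truth."""
    return make_nuclei_image(FixtureSpec(seed=7))


def random_bimodal_image(seed: int, n: int = 10000) -> np.ndarray:
    """Random image with two intensity populations and a dense histogram."""
    rng = np.random.default_rng(seed)
    vals = np.concatenate(
        [rng.normal(80, 30, n // 2), rng.normal(170, 25, n - n // 2)]
    )
    side = int(np.sqrt(n))
    return np.clip(vals[: side * side], 0, 255).astype(np.uint8).reshape(side, side)
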