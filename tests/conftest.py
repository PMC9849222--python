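import numpy as np
import pytest

from lorentzmf.lorentz_core import lift_to_hyperboloid


def random_points(rng, n, d, scale=1.0):
    """Random hyperboloid points: lift of Gaussian space-like coordinates."""
    return lift_to_hyperboloid(rng.normal(0.0, scale, size=(n, d)))


def random_tangents(rng, base, scale=1.0):
    """Random tangent vectors at each row of ``base`` (Lorentz-orthogonal)."""
    from lorentzmf.lorentz_core import project_to_tangent

    raw = rng.normal(0.0, scale, size=base.shape)
    return project_to_tangent(base, raw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
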