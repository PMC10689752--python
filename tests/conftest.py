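import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_contact_cluster(rng, n):
    """Random overlap-free cluster: Gaussian cloud rescaled to contact."""
    from finpack.projection import rescale_to_contact

    pts = rng.normal(scale=1.5, size=(n, 3))
    cluster, _ = rescale_to_contact(pts, diameter=1.0)
    return cluster
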