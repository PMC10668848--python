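import numpy as np
import pytest
from hypothesis import settings

from openherd.synthetic import NuisanceConfig, generate_dataset, make_identities

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


def finite_difference(fn, x, eps=1e-6):
    """Central-difference gradient of scalar fn with respect to array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        lp = fn()
        x[i] = orig - eps
        lm = fn()
        x[i] = orig
        g[i] = (lp - lm) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small but realistic herd: 5 well-separated individuals, 2 days,
    3 sessions x 3 images, 32 px."""
    root = tmp_path_factory.mktemp("herd")
    ids = make_identities(5, sigma_id=2.0, seed=11)
    manifest = generate_dataset(
        ids, per_id_per_session=3, nuisance=NuisanceConfig(),
        out_dir=root, seed=11, size=32, days=("day1", "day2"),
    )
    return manifest
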