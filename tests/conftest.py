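import numpy as np
import pytest

from sonomil import load_bag_images, load_manifest
from sonomil.simulate import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """Small written cohort shared by IO/training smoke tests."""
    out = tmp_path_factory.mktemp("cohort")
    config = SynthConfig(n_patients=24, bag_size_range=(2, 4), seed=123)
    record = generate_cohort(config, out)
    return config, record


@pytest.fixture(scope="session")
def tiny_bags(tiny_cohort):
    _, record = tiny_cohort
    bags = load_manifest(record.manifest_path)
    for b in bags:
        load_bag_images(b, size=64)
    return bags


def numeric_grad(fn, arrs, idx, eps=1e-6):
    """Central-difference gradient of scalar ``fn`` w.r.t. ``arrs[idx]``."""
    a = [np.asarray(x, dtype=np.float64).copy() for x in arrs]
    g = np.zeros_like(a[idx])
    it = np.nditer(a[idx], flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        a[idx][i] += eps
        fp = fn(*a)
        a[idx][i] -= 2 * eps
        fm = fn(*a)
        a[idx][i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
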