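import numpy as np
import pytest

from triacyl import SynthSpec, SystemDescriptor, build_templates, generate_ensemble


@pytest.fixture(scope="session")
def cca_system():
    return SystemDescriptor("CCA", "ALA", "2p", "L")


@pytest.fixture(scope="session")
def cca_templates(cca_system):
    return build_templates(cca_system)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_mixture(cca_templates):
    """60-frame labelled mixture used by several geometric tests."""
    spec = SynthSpec(weights=(0.4, 0.3, 0.3), jitter_sigma=0.25, n_frames=60, seed=7)
    ensemble, labels = generate_ensemble(cca_templates, spec)
    return ensemble, labels


def random_rotation(rng):
    """Uniform proper rotation for rigid-motion invariance checks."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
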