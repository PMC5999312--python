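import pytest

from panhe import SimConfig
from panhe.pav import PAVParams, build_pav_matrix, call_pav
from panhe.simulate import simulate_dataset


def _pipeline(config):
    truth, tracks = simulate_dataset(config)
    calls = {a: call_pav(truth.annotation, tracks[a], PAVParams())
             for a in truth.accessions}
    matrix, excluded = build_pav_matrix(calls, tracks)
    return truth, tracks, calls, matrix


@pytest.fixture(scope="session")
def noisefree_data():
    """Default study conditions, exact depths (no Poisson noise)."""
    return _pipeline(SimConfig(seed=1, depth_noise="none"))


@pytest.fixture(scope="session")
def noisy_data():
    """Default study conditions with Poisson depth noise at 12x."""
    return _pipeline(SimConfig(seed=2))


@pytest.fixture(scope="session")
def noisy_many_he_data():
    """Larger noisy panel carrying >= 50 true exchange events."""
    return _pipeline(SimConfig(seed=3, n_accessions=80))
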