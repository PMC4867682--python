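import pytest

from isodil.partition import SeedPModel
from isodil.synthetic import default_truth, simulate_pot_experiment


@pytest.fixture()
def seed_model():
    return SeedPModel(a=0.04, b=0.5)


@pytest.fixture()
def noiseless_pot():
    """Zero-noise pot experiment: (plants, fertilizers, truth)."""
    truth = default_truth(seed=0)
    return simulate_pot_experiment(truth, seed=0, noise_cv_p=0.0, noise_cv_activity=0.0)


@pytest.fixture()
def noisy_pot():
    """Seeded pot experiment at the default CV (5% P, 2% activity)."""
    truth = default_truth(seed=11)
    return simulate_pot_experiment(truth, seed=11, noise_cv_p=0.05, noise_cv_activity=0.02)
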