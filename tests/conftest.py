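import pytest
from hypothesis import settings

from standflux import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_dataset():
    """One synthetic tropical year with exact (noise-free) observations."""
    cfg = synthetic.SyntheticConfig(obs_cv=0.0)
    return synthetic.generate_dataset(cfg, seed=1)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default synthetic year with 10% multiplicative observation noise."""
    return synthetic.generate_dataset(synthetic.SyntheticConfig(), seed=42)
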