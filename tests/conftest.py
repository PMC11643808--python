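import pytest

from dietsig.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_bundle():
    """A compact two-wave cohort with a strong planted diet-lipid coupling."""
    cfg = GeneratorConfig(seed=7, n_train=260, n_test=140, n_lipids=80,
                          n_signal_lipids=10, diet_lipid_coupling=0.5)
    return generate(cfg)
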