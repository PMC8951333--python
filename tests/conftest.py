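import pytest

from strokekit.phantoms import PhantomSpec, generate_perfusion_phantom


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_sd=0.0, hemoglobin_noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_perfusion_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(seed=7)  # defaults: noise SD 2 % of baseline
    return spec, *generate_perfusion_phantom(spec)
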