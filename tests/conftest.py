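import numpy as np
import pytest

from pulpgan.phantom import PhantomConfig, generate_batch_arrays, generate_phantom


SMOKE_PHANTOM = dict(height=32, width=32, n_teeth=2, boundary_thickness=1,
                     lesion_rate=0.7, noise_sd=0.02)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_sample():
    """One 32x32 phantom with all three anatomical masks populated."""
    return generate_phantom(PhantomConfig(seed=3, **SMOKE_PHANTOM))


@pytest.fixture(scope="session")
def phantom_batch():
    """16 smoke-scale phantoms (the reference desk-scale training set)."""
    return generate_batch_arrays(PhantomConfig(seed=0, **SMOKE_PHANTOM), 16)


@pytest.fixture(scope="session")
def tiny_specs():
    from pulpgan.gan import DiscriminatorSpec, GeneratorSpec
    gen = GeneratorSpec(latent_dim=16, output_resolution=32, output_channels=1,
                        width_multiplier=1 / 32,
                        dense_block_growth_rates=(4, 4, 4, 4))
    disc = DiscriminatorSpec(input_resolution=32, input_channels=1,
                             width_multiplier=1 / 32)
    return gen, disc
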