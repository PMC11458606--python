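import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_gan():
    """A briefly trained 16x16 GAN shared by feature/extraction tests."""
    from ganb import gan, phantom

    specs = [phantom.PhantomSpec(image_size=16, vessel_radius=6.0, noise_sd=0.01,
                                 stenosis_fraction=f, seed=i)
             for i, f in enumerate([0.1, 0.3, 0.5, 0.8] * 4)]
    data = np.stack([phantom.generate_phantom(s).image for s in specs])
    cfg = gan.TrainConfig(epochs=10, batch_size=8, image_size=16, seed=5,
                          optimizer="adam", learning_rate=2e-3)
    G, D, rec = gan.train_gan(data, cfg)
    return G, D, cfg, data
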