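import numpy as np
import pytest
from hypothesis import settings

import wdbcm as wb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pair04():
    return wb.make_pair2d(0.4)


@pytest.fixture(scope="session")
def pair_cfg():
    return wb.PlasticityConfig(rule="standard", tau_theta=20, tau_w=200, rng_seed=3)


@pytest.fixture(scope="session")
def pair_standard_run(pair04, pair_cfg):
    """Converged noiseless standard-BCM run on the phi=0.4 pair."""
    return wb.simulate(pair04, pair_cfg, n_presentations=40_000, record_every=500)


@pytest.fixture(scope="session")
def pair_wd_cfg():
    return wb.PlasticityConfig(
        rule="weight_dependent", u=1.3, tau_theta=20, tau_w=200, rng_seed=3
    )


@pytest.fixture(scope="session")
def pair_wd_run(pair04, pair_wd_cfg):
    """Converged weight-dependent run at weak inhibition (u=1.3)."""
    return wb.simulate(pair04, pair_wd_cfg, n_presentations=60_000, record_every=500)


@pytest.fixture(scope="session")
def triangular20():
    return wb.make_triangular(20, 20, 0.5)


@pytest.fixture(scope="session")
def triangular_standard_run(triangular20):
    """Standard BCM trained to winner-take-all on 20 triangular stimuli."""
    cfg = wb.PlasticityConfig(
        rule="standard",
        tau_theta=200,
        tau_w=2000,
        rng_seed=11,
        transfer=wb.TransferSpec("rectified"),
    )
    return wb.simulate(triangular20, cfg, n_presentations=1_200_000, record_every=20_000)


@pytest.fixture(scope="session")
def triangular_wd_sweep(triangular20):
    """Weight-dependent runs across inhibition levels (ascending u)."""
    out = {}
    for u in (0.5, 2.0, 5.0, 10.0):
        cfg = wb.PlasticityConfig(
            rule="weight_dependent",
            u=u,
            tau_theta=200,
            tau_w=2000,
            rng_seed=11,
            transfer=wb.TransferSpec("rectified"),
        )
        out[u] = wb.simulate(triangular20, cfg, n_presentations=300_000, record_every=20_000)
    return out


@pytest.fixture(scope="session")
def synthetic_images():
    return wb.generate_synthetic_images(6, 128, seed=42)


@pytest.fixture(scope="session")
def image_patch_config():
    return wb.ImagePipelineConfig(patch_pixels=100, n_patches=1000, rng_seed=3)


@pytest.fixture(scope="session")
def zero_mean_patches(synthetic_images, image_patch_config):
    return wb.make_image_patches(synthetic_images, image_patch_config, zero_mean=True)


@pytest.fixture(scope="session")
def positive_patches(synthetic_images, image_patch_config):
    return wb.make_image_patches(synthetic_images, image_patch_config, zero_mean=False)
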