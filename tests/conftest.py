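import numpy as np
import pytest
from hypothesis import settings

from ftirbone import synthetic as syn
from ftirbone import spectral as sp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def noise_free_config(**kwargs) -> syn.GeneratorConfig:
    cfg = syn.GeneratorConfig(map_noise=0.0, **kwargs)
    cfg.pixel_sds = {k: 0.0 for k in cfg.pixel_sds}
    return cfg


PLANTED = {"mmr": 4.4, "cpr": 0.009, "crystallinity": 1.12, "xlr": 3.4}


@pytest.fixture(scope="session")
def noise_free_map():
    """Deterministic map whose every pixel encodes the same planted ratios."""
    cfg = noise_free_config()
    latents = {f"latent_{p}": v for p, v in PLANTED.items()}
    return syn.generate_spectral_map(latents, cfg, seed=3), PLANTED


@pytest.fixture(scope="session")
def noise_free_pixel_table(noise_free_map):
    smap, planted = noise_free_map
    return sp.extract_pixel_table(smap), planted


@pytest.fixture(scope="session")
def planted_cohort():
    """n=200 cohort with the default planted change-point/fracture structure."""
    cohort, truth, thresholds = syn.simulate_cohort(
        syn.GeneratorConfig(n_patients=200), seed=11
    )
    return cohort, truth, thresholds


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth, thresholds = syn.simulate_cohort(
        syn.GeneratorConfig(n_patients=40), seed=5
    )
    return cohort, truth, thresholds
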