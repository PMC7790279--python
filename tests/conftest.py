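import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dynaleak.phantom import preset_config, generate_phantom
from dynaleak.tac import extract_tac

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(preset: str, noise_sd: float = 0.0, seed: int = 0):
    """Down-scaled phantom grid (24x32x32 @ 5x3x3 mm) for fast unit tests;
    kinetics identical to the full presets."""
    from dataclasses import replace

    conf = preset_config(preset, noise_sd=noise_sd, rng_seed=seed)
    conf = replace(conf, shape=(24, 32, 32), spacing=(5.0, 3.0, 3.0),
                   sac_z_range_mm=(20.0, 100.0))
    if preset in ("single-leak", "paper-calibrated"):
        conf = replace(conf, blobs=(replace(conf.blobs[0], center_mm=(60.0, 18.0, 0.0)),))
    elif preset == "two-feeder":
        conf = replace(conf, blobs=(
            replace(conf.blobs[0], center_mm=(45.0, 18.0, 0.0)),
            replace(conf.blobs[1], center_mm=(80.0, -18.0, 0.0)),
        ))
    return conf


@pytest.fixture(scope="session")
def clean_leak_phantom():
    """Noiseless small single-leak phantom (volume, truth)."""
    return generate_phantom(small_config("paper-calibrated"))


@pytest.fixture(scope="session")
def noisy_leak_phantom():
    """Small single-leak phantom with 10 HU noise, seed 0."""
    return generate_phantom(small_config("paper-calibrated", noise_sd=10.0))


@pytest.fixture()
def aif_of():
    """AIF extractor: mean lumen TAC over the cranial-most lumen slices."""

    def _extract(volume, truth, n_slices: int = 4):
        m = truth.lumen_mask.copy()
        m[n_slices:] = False
        return extract_tac(volume, m, "aortic_lumen", role="AIF")

    return _extract


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
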