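import numpy as np
import pytest

from filasim.parameters import ThetaParams, default_theta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_theta() -> ThetaParams:
    """Reduced-cost θ for pipeline tests: small canvas, few short filaments."""
    return default_theta().replace(
        image_h=128, image_w=128,
        count_mean=4, count_sd=1,
        fil_len_mean=60, fil_len_sd=15,
        seed_len=8,
    )


@pytest.fixture
def clean_theta(small_theta) -> ThetaParams:
    """small_theta with every degradation amplitude off (noise-free renders)."""
    return small_theta.replace(
        noise_gauss_sd=0.0, photon_scale=0.0, speckle_sd=0.0,
        vignette_strength=0.0, blur_sigma=0.0, bgfield_amp=0.0,
        n_spots_mean=0.0, channel_jitter_sd=0.0,
    )


def circle_polyline(radius: float, center: tuple[float, float],
                    n: int = 3000) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n)
    return np.stack([center[0] + radius * np.cos(t),
                     center[1] + radius * np.sin(t)], axis=1)
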