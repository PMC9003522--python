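import numpy as np
import pytest

import avfpulse as ap

VESSEL_WIDTH = 2 * ap.PhantomConfig().vessel_halfwidth + 1  # in-phase extent, px


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """Small, fast phantom with default amplitudes (regions unchanged)."""
    cfg = ap.PhantomConfig(height=21, width=111, vessel_center=55, seed=7)
    stack, truth = ap.generate_phantom(cfg)
    return cfg, stack, truth


@pytest.fixture
def noiseless_phantom():
    """Unquantized, noise-free phantom for exact-identity checks."""
    cfg = ap.PhantomConfig(
        height=11,
        width=111,
        vessel_center=55,
        noise_sigma=0.0,
        thrill_amp=0.0,
        quantize=False,
        tint=(1.0, 1.0, 1.0),
        seed=0,
    )
    stack, truth = ap.generate_phantom(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def default_sweeps():
    """Full kernel sweeps on the default phantom over 20 seeds.

    Shared by the SNR-curve-shape and kernel-recovery checks; the
    default scene is the published acquisition (40 fps, 10 s) with the
    full 1..201 sweep.
    """
    results = []
    for seed in range(20):
        cfg = ap.PhantomConfig(seed=seed)
        stack, _ = ap.generate_phantom(cfg)
        lum = ap.to_channel(stack, "luminance")
        roi = (cfg.height // 2, cfg.vessel_center)
        results.append(ap.snavf_sweep(lum, roi))
    return results
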