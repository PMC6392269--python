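import numpy as np
import pytest

import csfhydro as ch


@pytest.fixture(scope="session")
def default_config() -> ch.PhantomConfig:
    return ch.PhantomConfig()


@pytest.fixture(scope="session")
def default_geometry(default_config):
    """Rasterized default phantom plus its analytic ground truth."""
    return ch.generate_geometry(default_config)


@pytest.fixture(scope="session")
def default_profile(default_geometry):
    seg, _ = default_geometry
    return ch.slice_profiles(seg)


def constant_annulus(r_cord: float, r_dura: float, pixel_mm: float = 0.375,
                     n_slices: int = 3, grid_n: int = 96) -> ch.SegmentationVolume:
    """Concentric-annulus volume with identical slices, for closed-form oracles."""
    half = grid_n * pixel_mm / 2.0
    c = (np.arange(grid_n) + 0.5) * pixel_mm - half
    xx, yy = np.meshgrid(c, c, indexing="ij")
    rr2 = xx**2 + yy**2
    cord2d = rr2 <= r_cord**2
    dura2d = rr2 <= r_dura**2
    cord = np.repeat(cord2d[:, :, None], n_slices, axis=2)
    dura = np.repeat(dura2d[:, :, None], n_slices, axis=2)
    return ch.SegmentationVolume(cord=cord, dura=dura,
                                 spacing=(pixel_mm, pixel_mm, 1.0))


def sinusoid_waveform(q0: float = 0.5, period: float = 0.5, n: int = 24,
                      z: float = 0.0, phase: float = 0.0) -> ch.FlowWaveform:
    t = np.arange(n) * period / n
    return ch.FlowWaveform(z_mm=z, q_ml_s=q0 * np.sin(2 * np.pi * (t / period) + phase),
                           period_s=period)
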