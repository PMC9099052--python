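import dataclasses

import numpy as np
import pytest

from fosters.config import (AcquisitionParams, GeometryConfig, MotionConfig,
                            PhantomConfig, ReconConfig)
from fosters import phantom, sampling


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def small_config(**overrides) -> PhantomConfig:
    """A 48x48, 24-frame phantom that keeps every unit test fast."""
    geometry = GeometryConfig(
        lv_center=(26.0, 26.0), lv_radius=6.0, myo_outer_radius=10.0,
        fat_outer_radius=12.0, rv_center=(26.0, 9.0), rv_radius=4.0,
        chest_fat_rows=(4, 7))
    base = dict(grid_size=(48, 48), n_frames=24, geometry=geometry,
                motion=MotionConfig(amplitude=2.0, amplitude_lr=1.0),
                defect=None, n_coils=3, seed=7)
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture()
def small_cfg() -> PhantomConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_truth():
    return phantom.render_truth(small_config())


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth at the full default study conditions (96x96, 40 frames)."""
    return phantom.render_truth(PhantomConfig())


@pytest.fixture(scope="session")
def small_kt():
    """Noisy undersampled acquisition of the small phantom (R=4)."""
    cfg = small_config()
    pattern = sampling.generate_kt_mask(48, 48, cfg.n_frames, 4, 0.08,
                                        seed=cfg.seed)
    truth, kt = phantom.simulate_acquisition(cfg, pattern)
    return truth, kt


@pytest.fixture()
def fast_recon_cfg() -> ReconConfig:
    return ReconConfig(n_iter=10)


@pytest.fixture()
def acq() -> AcquisitionParams:
    return AcquisitionParams()


def no_decay_acq() -> AcquisitionParams:
    """Acquisition with T2* effects switched off (pure Dixon inversion)."""
    return dataclasses.replace(AcquisitionParams(), t2star_0=1e9,
                               r2star_relaxivity=0.0)
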