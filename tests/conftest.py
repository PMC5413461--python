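"""Shared fixtures: session-scoped phantoms and noise-calibrated presets."""

import dataclasses
import warnings

import numpy as np
import pytest

from apatitemap.phantoms import (
    BoneSampleSpec,
    RatHeadSpec,
    make_bone_sample_phantom,
    make_rat_head_phantom,
)
from apatitemap.volume import centered_grid
from apatitemap.zte_sim import ZTEParams, calibrate_noise_sd


@pytest.fixture(scope="session")
def head_phantom():
    return make_rat_head_phantom()


@pytest.fixture(scope="session")
def bone_phantom():
    return make_bone_sample_phantom()


@pytest.fixture(scope="session")
def zte_default():
    return ZTEParams()


@pytest.fixture(scope="session")
def calib_params(bone_phantom):
    """Calibration-scan preset: 96 averages, noise pinned to bone SNR 30."""
    base = ZTEParams(n_averages=96)
    return dataclasses.replace(
        base, noise_sd=calibrate_noise_sd(bone_phantom, base, 30.0)
    )


@pytest.fixture(scope="session")
def invivo_params(head_phantom):
    """In-vivo preset: 16 averages, noise pinned to skull SNR 10."""
    base = ZTEParams(n_averages=16)
    return dataclasses.replace(
        base, noise_sd=calibrate_noise_sd(head_phantom, base, 10.0)
    )


@pytest.fixture
def uniform_bone_block():
    """A 22.4 mm cube of pure cortical bone centered in a 44.8 mm grid."""
    from apatitemap.phantoms import MATERIALS, Phantom
    from apatitemap.config import defaults

    grid = centered_grid((32, 32, 32), (1.4, 1.4, 1.4), semantics="labels")
    block = np.zeros(grid.shape, dtype=bool)
    block[8:24, 8:24, 8:24] = True
    labels = np.where(block, MATERIALS["cortical_bone"], MATERIALS["air"])
    apatite = float(defaults()["composition"]["apatite_p31_mol_per_l"])
    return Phantom(
        labels=grid.like(labels.astype(np.int16)),
        apatite_p31_molar=grid.like(np.where(block, apatite, 0.0)),
        mobile_p31_molar=grid.like(np.zeros(grid.shape)),
        activity=grid.like(np.zeros(grid.shape)),
        mu_true=grid.like(np.where(block, 0.1260612, 0.0)),
        spec=None,
    )


@pytest.fixture(autouse=True)
def _quiet_partial_volume_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="skull shell thinner than the voxel spacing"
        )
        yield
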