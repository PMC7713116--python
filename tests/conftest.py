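"""Shared fixtures: small seeded phantoms reused across test modules."""

import numpy as np
import pytest

from maculaflow.geometry import RoiSpec, circular_roi_mask
from maculaflow.phantom import DomeSpec, PhantomConfig, generate_volume


def make_domes(rng, n, field_um=5988.0, radius_range=(150.0, 400.0),
               peak_range=(30.0, 100.0), margin_um=800.0):
    """Random drusen wholly inside the field."""
    return tuple(
        DomeSpec(center_row_um=rng.uniform(margin_um, field_um - margin_um),
                 center_col_um=rng.uniform(margin_um, field_um - margin_um),
                 radius_um=rng.uniform(*radius_range),
                 peak_um=rng.uniform(*peak_range))
        for _ in range(n))


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Small noiseless phantom: 96x96 over 6 mm, default layer stack."""
    return PhantomConfig(grid_rows=96, grid_cols=96, lateral_pitch_um=62.5,
                         speckle_shape=None)


@pytest.fixture(scope="session")
def noiseless_volume(noiseless_cfg):
    return generate_volume(noiseless_cfg)


@pytest.fixture(scope="session")
def noisy_drusen_cfg():
    """Speckled phantom with a handful of drusen on a mid-size grid."""
    rng = np.random.default_rng(11)
    return PhantomConfig(grid_rows=160, grid_cols=160, lateral_pitch_um=37.5,
                         drusen_spec=make_domes(rng, 6), seed=11)


@pytest.fixture(scope="session")
def noisy_drusen_volume(noisy_drusen_cfg):
    return generate_volume(noisy_drusen_cfg)


@pytest.fixture()
def roi_500():
    return circular_roi_mask((500, 500), 12.0, RoiSpec(249.5, 249.5, 5.0))
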