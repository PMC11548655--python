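import numpy as np
import pytest

import flarekit as fk
from flarekit import inscribed_square_roi


@pytest.fixture()
def clean_noise():
    """Noise model with everything off: P-channel budget 160 counts/pixel at
    r_base=0.30 corresponds to total I = 300 photons/pixel."""
    return fk.NoiseSpec(photons_per_cell_pixel=160.0, read_sd=0.0, offset=0.0,
                        background_photons=0.0)


@pytest.fixture()
def small_scene(clean_noise):
    """3-cell noise-free scene, 64x128 dual view, 6 pre + 8 post frames."""
    acq = fk.AcquisitionSpec(half_view_shape=(64, 64), n_frames_post=8)
    return fk.make_scene(3, noise=clean_noise, acquisition=acq, seed=11)


@pytest.fixture()
def roi_polygons(small_scene):
    return {k: inscribed_square_roi(small_scene.cell_masks, k)
            for k in small_scene.cell_labels}
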