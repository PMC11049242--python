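import numpy as np
import pytest

from gliaquant.volume import LabeledVolume


@pytest.fixture(scope="session")
def ball_volume():
    """Digital ball, radius 20 voxels, isotropic 1 µm."""
    zz, yy, xx = np.ogrid[:45, :45, :45]
    ball = ((zz - 22) ** 2 + (yy - 22) ** 2 + (xx - 22) ** 2) <= 400
    return LabeledVolume(ball.astype(np.uint8), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def cube_volume():
    """Digital cube, side 20 voxels, isotropic 1 µm."""
    cube = np.zeros((26, 26, 26), np.uint8)
    cube[3:23, 3:23, 3:23] = 1
    return LabeledVolume(cube, (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def branched_cell():
    """One seeded synthetic cell with 8 processes of 25 µm + secondaries."""
    from gliaquant import synthdata

    truth = synthdata.ShapeTruth(
        soma_radius=5.0,
        n_processes=8,
        process_lengths=[25.0] * 8,
        has_secondary_branches=True,
    )
    return synthdata.gen_microglia(truth, seed=1)
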