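import numpy as np
import pytest

from mitograd import synthetic as syn


@pytest.fixture(scope="session")
def noise_free_scene() -> syn.SyntheticScene:
    """Small deterministic field with optics but no noise."""
    return syn.default_scene(seed=5, noise=False)


@pytest.fixture(scope="session")
def histamine_run():
    """One seeded histamine time-lapse with a programmed fission event."""
    scene = syn.default_scene(seed=7, noise=True)
    protocol = syn.Protocol(
        kind="histamine",
        n_frames=14,
        frame_interval=5.0,
        stimulus_time=20.0,
        fission_times=(40.0,),
    )
    return syn.simulate_timelapse(scene, protocol)


@pytest.fixture()
def gaussian_spot():
    """Constant background 50 plus a sigma=3 px Gaussian spot of amplitude 200."""
    yy, xx = np.mgrid[:120, :120]
    spot = 200.0 * np.exp(-((yy - 60) ** 2 + (xx - 60) ** 2) / (2 * 3.0**2))
    return 50.0 + spot, spot
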