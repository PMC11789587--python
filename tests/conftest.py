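import numpy as np
import pytest

import dogscreen as dg
from dogscreen.screen_assembly import annotate_parameters, merge_replicates
from dogscreen.synth_screen import Condition


@pytest.fixture(scope="session")
def layouts():
    return dg.default_layouts()


@pytest.fixture(scope="session")
def model():
    return dg.ResponseModel()


@pytest.fixture(scope="session")
def cond_main():
    """The responsive condition: 7 days with TGF-beta."""
    return Condition("7d", True)


@pytest.fixture(scope="session")
def sim_merged(model, layouts):
    """A full synthetic screen summarised from ground truth (no imaging),
    annotated with parameters and replicate-merged: 660 tiles, n = 2."""
    tab = dg.simulate_summary_table(model, layouts, seed=11, replicates=2)
    return merge_replicates(annotate_parameters(tab, layouts))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def quiet_optics():
    """Noise-free optics at 1 um/px for ground-truth-exact rendering tests."""
    return dg.OpticsConfig(
        pixel_size_um=1.0,
        camera_offset=0.0,
        read_noise_sd=0.0,
        shot_noise=False,
        background={"nuclei": 0.0, "asma": 0.0, "col1": 0.0},
        bg_gradient_amplitude=0.0,
    )
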