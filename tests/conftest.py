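import numpy as np
import pytest

from vsimetry.synthetic import (
    BolusModel,
    PhantomSpec,
    SlideSpec,
    render_slide,
    simulate_sage_dataset,
)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small noiseless SAGE phantom shared across relaxometry/perfusion tests."""
    phantom = PhantomSpec(grid_shape=(16, 16, 4), noise_sigma=0.0, seed=0)
    return phantom, simulate_sage_dataset(phantom, BolusModel(), n_timepoints=40)


@pytest.fixture(scope="session")
def rendered_slide_50():
    """Slide with 50 non-touching vessels, radii 3-20 um, and its truth."""
    rng = np.random.default_rng(11)
    radii = rng.uniform(3.0, 20.0, 50)
    spec = SlideSpec(image_shape=(1024, 1024), um_per_px=2.0,
                     vessel_radii=tuple(radii), seed=11)
    rgb, truth = render_slide(spec)
    return spec, rgb, truth
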