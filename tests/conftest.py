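import numpy as np
import pytest

import melaflim as mf
from melaflim.io import AcquisitionMetadata


@pytest.fixture(scope="session")
def md_invitro():
    """In vitro timing: 3128 channels x 4 ps (window slightly over one period)."""
    return mf.metadata_invitro_2d()


@pytest.fixture(scope="session")
def md_invivo2d():
    """In vivo 2D timing: 256 channels x 48.8 ps."""
    return mf.metadata_invivo_2d()


@pytest.fixture(scope="session")
def md_clinical():
    """In vivo 3D clinical timing: 4 channels x 2.08 ns, with z-step."""
    return mf.metadata_invivo_3d()


@pytest.fixture(scope="session")
def md_clean():
    """Analytically clean timing: window = exactly one 12.5 ns period,
    decay peak exactly on a channel edge (1.332 = 333 x 4 ps)."""
    return AcquisitionMetadata(
        time_channel_width=0.004,
        n_time_channels=3125,
        rep_period=12.5,
        peak_position=1.332,
        pixel_size=0.4,
    )


def noiseless_histogram(params, metadata, scale=1000.0):
    """Quasi-noiseless decay: the analytic expectation, scaled and rounded."""
    expectation = mf.expected_decay(params, metadata)
    return mf.DecayHistogram(
        np.round(expectation * scale).astype(np.int64), metadata
    )


@pytest.fixture(scope="session")
def small_phantom(md_clinical):
    """Reduced skin phantom shared by unit tests (32 x 48 x 48)."""
    spec = mf.default_phantom_spec(seed=11, shape=(32, 48, 48))
    stack, truth = mf.simulate_skin_stack(spec, md_clinical)
    return spec, stack, truth
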