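import warnings

import numpy as np
import pytest

from fntdose.synthetic import FieldConfig, GroundTruthTrack, NoiseConfig, render_stack

# rendering warns about tracks sampled outside the field of view; that is
# expected behaviour in these tests, not a failure signal
warnings.filterwarnings("ignore", message="track .* lies outside")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_config():
    """Field configuration with noise switched off: deterministic rendering."""
    return FieldConfig(noise=NoiseConfig(background_sd=0.0, shot_noise=False))


@pytest.fixture
def default_config():
    return FieldConfig()


def make_track(theta=0.0, azimuth=0.0, let=4.0, entry=(50.0, 50.0),
               residual=1000.0, kind="ion", species="proton"):
    return GroundTruthTrack(species_label=species, let_water=let,
                            polar_deg=theta, azimuth_deg=azimuth,
                            entry_xy=entry, residual_depth=residual, kind=kind)


@pytest.fixture
def single_track_stack(noiseless_config):
    """One 45-degree ion track rendered without noise."""
    track = make_track(theta=45.0, azimuth=0.0, entry=(30.0, 50.0))
    stack, manifest = render_stack([track], noiseless_config,
                                   np.random.default_rng(0))
    return stack, manifest, track
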