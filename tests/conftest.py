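import numpy as np
import pytest

from thetapupil.forward import HeadModel, compute_leadfield
from thetapupil.montage import equidistant_montage
from thetapupil.synthetic_data import Cohort, SimConfig


@pytest.fixture(scope="session")
def montage16():
    return equidistant_montage(16)


@pytest.fixture(scope="session")
def montage60():
    return equidistant_montage(60)


@pytest.fixture(scope="session")
def leadfield16(montage16):
    names, pos = montage16
    return compute_leadfield(HeadModel(), pos, spacing=0.012, ch_names=names)


@pytest.fixture(scope="session")
def leadfield16_1cm(montage16):
    names, pos = montage16
    return compute_leadfield(HeadModel(), pos, spacing=0.01, ch_names=names)


def small_cfg(**overrides) -> SimConfig:
    """Scaled-down two-session study configuration for fast tests."""
    base = dict(
        n_subjects=4,
        n_sessions=2,
        trials_per_session=10,
        n_channels=16,
        theta_amp_by_session=(60.0, 48.0),
        coupling_by_session=(-0.65, 0.0),
        pupil_amp_by_session=(0.070, 0.052),
        long_fixation_s=15.0,
        n_short_fixations=3,
        short_fixation_s=5.0,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort(leadfield16):
    return Cohort(small_cfg(), leadfield=leadfield16)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
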