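import numpy as np
import pytest

from alphaphase.config import SimConfig, SpectralSpec, StudyConfig
from alphaphase import synth


@pytest.fixture(scope="session")
def spectral_spec():
    return SpectralSpec()


@pytest.fixture(scope="session")
def small_session():
    """One light-weight participant session with all effects switched on."""
    cfg = SimConfig(n_participants=1, n_trials_by_cell=(120, 40, 16, 8),
                    phase_effect_depth=0.15, epoch_span=(-0.3, 0.1),
                    blink_rate=0.0, saccade_rate=0.0, erp_amp=0.0, seed=11)
    return synth.generate_session(cfg, 0, include_eog=False)


@pytest.fixture(scope="session")
def eog_session():
    """A session with ocular artifacts, full-length records."""
    cfg = SimConfig(n_participants=1, n_trials_by_cell=(120, 40, 16, 8),
                    seed=5)
    return synth.generate_session(cfg, 0)


@pytest.fixture(scope="session")
def tiny_study():
    """Ten-participant scaled-down study configuration."""
    return StudyConfig(
        sim=SimConfig(n_participants=10, n_trials_by_cell=(160, 56, 24, 8),
                      phase_effect_depth=0.15, blink_rate=0.0,
                      saccade_rate=0.0, epoch_span=(-0.3, 0.1), erp_amp=0.0,
                      seed=21),
        run_artifact_screen=False,
        n_perm_electrode=1999, n_perm_time=1999, n_perm_moore=1999,
        min_trials_per_response=10, analysis_seed=99)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
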