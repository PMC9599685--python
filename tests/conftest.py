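import numpy as np
import pytest

from aimnet.pipeline import PipelineSettings
from aimnet.simulate import CouplingSpec, simulate_subject

from _utils import small_config


@pytest.fixture(scope="session")
def settings() -> PipelineSettings:
    return PipelineSettings()


@pytest.fixture(scope="session")
def coupled_subject():
    """One subject with a strong planted beta-band C3-C4 coupling."""
    cfg = small_config(
        n_subjects=1,
        coupling_specs=(CouplingSpec(pair=("C3", "C4"), band="beta",
                                     phase_lag=np.pi / 4, strength=0.9),),
        subject_coupling_sd=0.0,
        seed=7,
    )
    return cfg, simulate_subject(cfg, 0)


@pytest.fixture(scope="session")
def plain_subject():
    """One subject with no planted coupling and no artifacts."""
    cfg = small_config(n_subjects=1, seed=11)
    return cfg, simulate_subject(cfg, 0)
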