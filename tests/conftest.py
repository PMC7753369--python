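import numpy as np
import pytest

from msvdfuse.synthgen import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """A fast session: 5 classes x 10 trials, full channel complement."""
    return SynthConfig(seed=7, trials_per_class=10)


@pytest.fixture(scope="session")
def default_session():
    """One session at the study conditions (5 classes, 40 trials/class,
    seed 42), prepared once and shared by the slower end-to-end tests."""
    from msvdfuse.pipeline import RunConfig, prepare_session

    cfg = RunConfig(seed=42, synth=SynthConfig(seed=42))
    return cfg, prepare_session(cfg)
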