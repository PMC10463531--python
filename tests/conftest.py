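import numpy as np
import pytest

from pactacs import synth, task


@pytest.fixture(scope="session")
def schedule():
    """One deterministic full 144-trial session schedule."""
    return task.build_schedule("pre", seed=2024)


@pytest.fixture(scope="session")
def clean_recording(schedule):
    """A preprocessed-ready synthetic recording with no artifacts."""
    spec = synth.SyntheticSubjectSpec(seed=7)
    return synth.gen_eeg(spec, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
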