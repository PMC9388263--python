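import numpy as np
import pytest

from eegmci import CohortSpec, gen_cohort
from eegmci.core import CANONICAL_CHANNELS, EEGRecording, Label


@pytest.fixture(scope="session")
def small_cohort():
    """3+3 subjects, 8 s at 128 Hz, default MCI/HC contrasts."""
    spec = CohortSpec(n_mci=3, n_hc=3, duration_s=8.0, fs=128.0, seed=42)
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def one_segment(small_cohort):
    return small_cohort[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=128.0, subject_id="s0", label=Label.UNKNOWN):
    return EEGRecording(
        data=np.asarray(data, dtype=float),
        fs=fs,
        channels=CANONICAL_CHANNELS[: np.asarray(data).shape[0]],
        subject_id=subject_id,
        label=label,
    )
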