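import numpy as np
import pandas as pd
import pytest

from mblfp.io_formats import AnnotationTable, LfpTrace
from mblfp.synthetic import CohortSimConfig, HuddleParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_trace(rng):
    """10 s of white noise at 1024 Hz, 16-bit integer samples."""
    samples = rng.integers(-2000, 2000, size=10 * 1024)
    return LfpTrace(
        subject_id="m1", cohort_id="c01", condition="single",
        fs=1024.0, samples=samples,
    )


def make_annotations(states_by_subject, condition="single", huddle_by_subject=None):
    """Build an AnnotationTable from per-subject state lists."""
    frames = []
    for sid, states in states_by_subject.items():
        n = len(states)
        hud = huddle_by_subject.get(sid, [None] * n) if huddle_by_subject else [None] * n
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "second": np.arange(n),
                    "locomotive_state": states,
                    "huddle_group_id": pd.array(
                        [h if h is not None else pd.NA for h in hud], dtype="string"
                    ),
                }
            )
        )
    return AnnotationTable(df=pd.concat(frames, ignore_index=True), condition=condition)


def degenerate_transition(state_idx=0):
    """Transition matrix that absorbs into one state immediately."""
    m = np.zeros((3, 3))
    m[:, state_idx] = 1.0
    return m


def calibration_config(**overrides):
    """Cohort config isolating the HLR drivers: one fixed state, no huddles.

    Used for statistical calibration of the interbrain machinery, where
    behavioural variance would only dilute the planted coupling under test.
    """
    deg = degenerate_transition(0)
    defaults = dict(
        n_subjects=4,
        duration_s=1800,
        condition="group",
        state_transition=deg,
        huddled_transition=deg,
        non_huddled_transition=deg,
        huddle=HuddleParams(formation_rate=0.0),
        coupling_strength=0.0,
        band_sigma=0.02,
    )
    defaults.update(overrides)
    return CohortSimConfig(**defaults)
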