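"""Shared fixtures: a small synthetic cohort and a canonical single trial."""

import numpy as np
import pytest

from adsuppress.io import EventTimeline, Recording
from adsuppress.synthetic import CohortSpec, gen_cohort

SMALL_SPEC = CohortSpec(
    n_trials=6,
    n_success=3,
    n_channels=8,
    w1_duration_s=(3.0, 3.5),
    w2_duration_s=(4.0, 4.5),
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    return gen_cohort(SMALL_SPEC)


@pytest.fixture()
def simple_recording():
    """A plain white-noise trial with a hand-written timeline."""
    rng = np.random.default_rng(5)
    fs = 1000.0
    rec = Recording(
        signals=rng.standard_normal((9000, 4)),
        fs_hz=fs,
        channel_labels=[f"ch{i}" for i in range(4)],
        trial_id="t0",
        outcome="failure",
    )
    timeline = EventTimeline(
        markers=[("AD_Start", 0.5), ("Qes_Start", 3.5), ("AD_End", 8.5)]
    )
    return rec, timeline
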