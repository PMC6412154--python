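import numpy as np
import pytest

from dyadnirs.session import HbTimeSeries, SessionEvents

PIPELINE_DONE = (
    "converted",
    "artifact_removed",
    "filtered",
    "normalized",
    "baseline_subtracted",
    "resampled",
)

ZERO_OFFSETS = {
    (role, phase): (0.0, 0.0)
    for role in ("initial_provider", "responder")
    for phase in ("single_provider", "team", "debriefing")
}

ZERO_COUPLING = {
    "baseline": 0.0,
    "single_provider": 0.0,
    "team": 0.0,
    "debriefing": 0.0,
}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_events():
    """Baseline [0, 300), three phases, two rating times."""
    return SessionEvents(
        baseline=(0.0, 300.0),
        phases=[
            ("single_provider", 300.0, 700.0),
            ("team", 700.0, 1200.0),
            ("debriefing", 1200.0, 2100.0),
        ],
        rating_times=[400.0, 750.0],
        scenario_id="scn1",
        difficulty_class="medium",
        experience_level="Y1",
    )


def series_1hz(values, chromophore="HbO", t0=0.0, state=PIPELINE_DONE):
    return HbTimeSeries(
        participant_id="p",
        chromophore=chromophore,
        values=np.asarray(values, float),
        sample_rate=1.0,
        t0=t0,
        state=tuple(state),
    )
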