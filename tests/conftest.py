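import numpy as np
import pytest

from tiltasym import BeatSeries, Group, PhaseAnnotation

#: hand-worked Poincaré example used across the suite
WORKED_SERIES = np.array([800.0, 850.0, 820.0, 840.0, 790.0, 800.0])


@pytest.fixture
def worked_series():
    return WORKED_SERIES.copy()


def make_series(duration_s=900.0, rr_ms=800.0, sbp=115.0, dbp=75.0, subject="X", group=Group.VVS_NEG):
    """Constant-signal recording covering ``duration_s`` at a fixed RR."""
    n = int(duration_s * 1000.0 / rr_ms)
    rr = np.full(n, rr_ms)
    t = np.cumsum(rr) / 1000.0
    return BeatSeries(
        beat_time=t,
        rr=rr,
        sbp=np.full(n, sbp),
        dbp=np.full(n, dbp),
        subject_id=subject,
        group=group,
    )


@pytest.fixture
def flat_recording():
    """900 s constant recording with supine 0–480 s, tilt onset at 480 s."""
    series = make_series(duration_s=900.0)
    annotation = PhaseAnnotation(supine_start_s=0.0, tilt_onset_s=480.0, recording_end_s=900.0)
    return series, annotation
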