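"""Artifact rejection, exclusion rules and phase segmentation.

Non-sinus beats are detected with a quotient filter on the RR series: a beat
is flagged when its ratio to either neighbour falls strictly outside the
acceptance band [low, high] (canonically 0.8–1.2).  Flagged beats are masked,
never deleted, so the exclusion percentages of the tilt-test protocol stay
computable and Poincaré pairs spanning a bad beat are simply dropped
downstream.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .signals import BeatSeries, PhaseAnnotation, PhaseSegment

__all__ = [
    "FilterReport",
    "ExclusionReason",
    "ExclusionDecision",
    "quotient_filter",
    "censor_beats",
    "check_exclusion",
    "extract_segments",
]

#: Analysis window lengths (s): 5-min S/T windows, 3-min S1/T1/T2 windows.
LONG_WINDOW_S = 300.0
SHORT_WINDOW_S = 180.0
#: Minimum tilt-to-syncope interval (s) for a vasovagal subject to be analysable.
MIN_SYNCOPE_DELAY_S = 360.0


@dataclass(frozen=True)
class FilterReport:
    n_beats: int
    flagged_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.flagged_indices, dtype=int))
        object.__setattr__(self, "flagged_indices", idx)
        if len(idx) and (idx[0] < 0 or idx[-1] >= self.n_beats):
            raise ValueError("flagged index out of range")

    @property
    def n_flagged(self) -> int:
        return int(len(self.flagged_indices))

    @property
    def fraction_flagged(self) -> float:
        return self.n_flagged / self.n_beats


class ExclusionReason(str, enum.Enum):
    NONSINUS_GT_5PCT = "NONSINUS_GT_5PCT"
    BP_MISSING_GT_10PCT = "BP_MISSING_GT_10PCT"
    RECORDING_LT_5MIN = "RECORDING_LT_5MIN"
    SYNCOPE_LT_6MIN = "SYNCOPE_LT_6MIN"


@dataclass(frozen=True)
class ExclusionDecision:
    reasons: tuple[ExclusionReason, ...]

    @property
    def excluded(self) -> bool:
        return len(self.reasons) > 0


def quotient_filter(rr: np.ndarray, low: float = 0.8, high: float = 1.2) -> FilterReport:
    """Flag probable non-sinus beats by their RR quotients with neighbours.

    Beat ``i`` is flagged when ``rr[i]/rr[i+1]`` or ``rr[i]/rr[i-1]`` lies
    strictly outside the closed interval ``[low, high]``; the first and last
    beat use their single available neighbour.
    """
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 3:
        raise ValueError("quotient filter needs at least 3 beats")
    if not (0 < low < 1 < high):
        raise ValueError("thresholds must satisfy 0 < low < 1 < high")
    fwd = rr[:-1] / rr[1:]   # rr[i] / rr[i+1], defined for i in [0, n-2]
    bwd = rr[1:] / rr[:-1]   # rr[i] / rr[i-1], defined for i in [1, n-1]
    out = np.zeros(len(rr), dtype=bool)
    bad_fwd = (fwd < low) | (fwd > high)
    bad_bwd = (bwd < low) | (bwd > high)
    out[:-1] |= bad_fwd
    out[1:] |= bad_bwd
    return FilterReport(n_beats=len(rr), flagged_indices=np.flatnonzero(out))


def censor_beats(series: BeatSeries, report: FilterReport) -> BeatSeries:
    """Mask flagged beats (RR and both BP channels jointly); pure masking."""
    if report.n_beats != len(series):
        raise ValueError("filter report length does not match series")
    valid = series.valid.copy()
    valid[report.flagged_indices] = False
    return series.with_valid(valid)


def check_exclusion(
    series: BeatSeries,
    annotation: PhaseAnnotation,
    report: FilterReport,
    *,
    nonsinus_max: float = 0.05,
    bp_missing_max: float = 0.10,
) -> ExclusionDecision:
    """Apply the subject-level exclusion rules of the tilt-test protocol.

    A subject is excluded when the flagged-beat fraction exceeds 5%, the
    missing-BP fraction exceeds 10%, either analysis phase is shorter than
    its nominal 5 min, or (vasovagal subjects) syncope occurred less than
    6 min after tilt.  All thresholds are strict ("exceeds").
    """
    reasons: list[ExclusionReason] = []
    if report.fraction_flagged > nonsinus_max:
        reasons.append(ExclusionReason.NONSINUS_GT_5PCT)
    if series.bp_missing_fraction > bp_missing_max:
        reasons.append(ExclusionReason.BP_MISSING_GT_10PCT)
    if annotation.supine_duration_s < LONG_WINDOW_S or annotation.tilt_duration_s < LONG_WINDOW_S:
        reasons.append(ExclusionReason.RECORDING_LT_5MIN)
    if annotation.syncope_onset_s is not None:
        if annotation.syncope_onset_s - annotation.tilt_onset_s < MIN_SYNCOPE_DELAY_S:
            reasons.append(ExclusionReason.SYNCOPE_LT_6MIN)
    return ExclusionDecision(reasons=tuple(reasons))


def _window_segment(series: BeatSeries, label: str, start: float, end: float) -> PhaseSegment | None:
    try:
        sub = series.restrict(start, end)
    except ValueError:
        warnings.warn(f"segment {label}: window [{start}, {end}) holds fewer than 2 beats; omitted")
        return None
    return PhaseSegment(label=label, series=sub, window=(start, end))


def extract_segments(series: BeatSeries, annotation: PhaseAnnotation) -> dict[str, PhaseSegment]:
    """Cut the protocol's analysis windows out of a recording.

    S  : 300 s centred in the supine phase;
    T  : first 300 s of tilt;
    S1 : 180 s centred in the supine phase;
    T1 : first 180 s of tilt;
    T2 : last 180 s before syncope onset (when annotated).

    Beat membership is by half-open interval on beat_time.  A window longer
    than its source phase is omitted with a warning.
    """
    out: dict[str, PhaseSegment] = {}
    sup0, tilt0 = annotation.supine_start_s, annotation.tilt_onset_s
    sup_mid = 0.5 * (sup0 + tilt0)
    tilt_end = annotation.syncope_onset_s if annotation.syncope_onset_s is not None else annotation.recording_end_s

    for label, length in (("S", LONG_WINDOW_S), ("S1", SHORT_WINDOW_S)):
        if annotation.supine_duration_s < length:
            warnings.warn(f"segment {label}: supine phase shorter than {length:.0f} s; omitted")
            continue
        seg = _window_segment(series, label, sup_mid - length / 2, sup_mid + length / 2)
        if seg is not None:
            out[label] = seg

    for label, length in (("T", LONG_WINDOW_S), ("T1", SHORT_WINDOW_S)):
        if tilt_end - tilt0 < length:
            warnings.warn(f"segment {label}: tilt phase shorter than {length:.0f} s; omitted")
            continue
        seg = _window_segment(series, label, tilt0, tilt0 + length)
        if seg is not None:
            out[label] = seg

    if annotation.syncope_onset_s is not None:
        t2_start = annotation.syncope_onset_s - SHORT_WINDOW_S
        if t2_start < tilt0:
            warnings.warn("segment T2: less than 180 s of tilt before syncope; omitted")
        else:
            seg = _window_segment(series, "T2", t2_start, annotation.syncope_onset_s)
            if seg is not None:
                out["T2"] = seg
    return out
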