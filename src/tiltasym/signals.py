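"""Domain containers for beat-to-beat tilt-test recordings and their on-disk formats.

A recording is one row per heartbeat: cumulative time (s), RR interval (ms),
systolic and diastolic finger pressure (mmHg).  Pulse pressure is derived.
Beats with a missing blood-pressure sample, or flagged as non-sinus by the
artifact filter, stay in the series with ``valid=False`` so that exclusion
percentages remain computable.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Group",
    "BeatSeries",
    "PhaseAnnotation",
    "PhaseSegment",
    "read_beat_series",
    "write_beat_series",
    "read_phase_annotation",
    "write_phase_annotation",
    "write_summary_table",
    "read_summary_table",
]

SERIES_COLUMNS = ("beat_time_s", "rr_ms", "sbp_mmhg", "dbp_mmhg")


class Group(str, enum.Enum):
    """Study arm: vasovagal patients (positive tilt test) vs healthy controls."""

    VVS_POS = "VVS_POS"
    VVS_NEG = "VVS_NEG"


@dataclass
class BeatSeries:
    """Aligned per-beat vectors for one subject.

    Parameters
    ----------
    beat_time : array of float
        Seconds from recording start, strictly increasing.
    rr : array of float
        Heartbeat interval in ms.
    sbp, dbp : array of float
        Systolic / diastolic pressure in mmHg; NaN marks a missing sample.
    valid : array of bool, optional
        Per-beat analysis mask (sinus origin and BP present).  Defaults to
        "both BP samples present".
    """

    beat_time: np.ndarray
    rr: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    valid: np.ndarray | None = None
    subject_id: str = ""
    group: Group = Group.VVS_NEG

    def __post_init__(self) -> None:
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        n = len(self.beat_time)
        if n < 2:
            raise ValueError("a beat series needs at least 2 beats")
        for name in ("rr", "sbp", "dbp"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in field {name!r}")
        if self.valid is None:
            self.valid = np.isfinite(self.sbp) & np.isfinite(self.dbp)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != n:
                raise ValueError("length mismatch in field 'valid'")
        if np.any(np.diff(self.beat_time) <= 0):
            raise ValueError("beat_time must be strictly increasing")
        if np.any(self.rr[self.valid] <= 0):
            raise ValueError("RR must be positive on valid beats")
        if np.any(self.sbp[self.valid] <= self.dbp[self.valid]):
            raise ValueError("sBP must exceed dBP on valid beats")
        self.group = Group(self.group)

    @property
    def pp(self) -> np.ndarray:
        """Pulse pressure, sBP − dBP per beat (NaN where BP missing)."""
        return self.sbp - self.dbp

    @property
    def bp_missing_fraction(self) -> float:
        return float(np.mean(~np.isfinite(self.sbp) | ~np.isfinite(self.dbp)))

    def __len__(self) -> int:
        return len(self.beat_time)

    def signal(self, name: str) -> np.ndarray:
        """Return one of the per-beat channels: 'rr', 'sbp', 'dbp' or 'pp'."""
        if name not in ("rr", "sbp", "dbp", "pp"):
            raise KeyError(f"unknown signal {name!r}")
        return getattr(self, name)

    def restrict(self, start_s: float, end_s: float) -> "BeatSeries":
        """Sub-series of beats whose beat_time lies in [start_s, end_s)."""
        m = (self.beat_time >= start_s) & (self.beat_time < end_s)
        if m.sum() < 2:
            raise ValueError("window contains fewer than 2 beats")
        return BeatSeries(
            beat_time=self.beat_time[m],
            rr=self.rr[m],
            sbp=self.sbp[m],
            dbp=self.dbp[m],
            valid=self.valid[m],
            subject_id=self.subject_id,
            group=self.group,
        )

    def with_valid(self, valid: np.ndarray) -> "BeatSeries":
        return dataclasses.replace(self, valid=np.asarray(valid, dtype=bool))


@dataclass(frozen=True)
class PhaseAnnotation:
    """Protocol timestamps for one recording, in seconds from start."""

    supine_start_s: float
    tilt_onset_s: float
    recording_end_s: float
    syncope_onset_s: float | None = None

    def __post_init__(self) -> None:
        if not (self.supine_start_s < self.tilt_onset_s < self.recording_end_s):
            raise ValueError("require supine_start < tilt_onset < recording_end")
        if self.syncope_onset_s is not None and not (
            self.tilt_onset_s < self.syncope_onset_s <= self.recording_end_s
        ):
            raise ValueError("syncope_onset must lie in (tilt_onset, recording_end]")

    @property
    def supine_duration_s(self) -> float:
        return self.tilt_onset_s - self.supine_start_s

    @property
    def tilt_duration_s(self) -> float:
        end = self.syncope_onset_s if self.syncope_onset_s is not None else self.recording_end_s
        return end - self.tilt_onset_s


@dataclass(frozen=True)
class PhaseSegment:
    """A named analysis window (S, T, S1, T1 or T2) cut out of a recording."""

    label: str
    series: BeatSeries
    window: tuple[float, float]


def read_beat_series(path: str | Path, subject_id: str = "", group: Group | str = Group.VVS_NEG) -> BeatSeries:
    """Read a delimited beat-to-beat recording.

    Expects a CSV with header columns ``beat_time_s, rr_ms, sbp_mmhg,
    dbp_mmhg``; an empty BP field marks a missing sample and yields
    ``valid=False`` for that beat.  A malformed numeric field raises a
    ``ValueError`` naming the offending line.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing_cols = [c for c in SERIES_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")

    def _col(name: str, allow_blank: bool) -> np.ndarray:
        vals = raw[name].to_numpy(dtype=object)
        out = np.empty(len(vals), dtype=float)
        for i, v in enumerate(vals):
            blank = v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""
            if blank:
                if allow_blank:
                    out[i] = np.nan
                    continue
                raise ValueError(f"{path}: line {i + 2}: empty value in column {name!r}")
            try:
                out[i] = float(v)
            except ValueError as exc:
                raise ValueError(f"{path}: line {i + 2}: cannot parse {v!r} in column {name!r}") from exc
        return out

    return BeatSeries(
        beat_time=_col("beat_time_s", allow_blank=False),
        rr=_col("rr_ms", allow_blank=False),
        sbp=_col("sbp_mmhg", allow_blank=True),
        dbp=_col("dbp_mmhg", allow_blank=True),
        subject_id=subject_id,
        group=group,
    )


def write_beat_series(series: BeatSeries, path: str | Path) -> None:
    """Write a recording in the schema `read_beat_series` expects."""
    df = pd.DataFrame(
        {
            "beat_time_s": series.beat_time,
            "rr_ms": series.rr,
            "sbp_mmhg": series.sbp,
            "dbp_mmhg": series.dbp,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")


def read_phase_annotation(path: str | Path) -> PhaseAnnotation:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PhaseAnnotation(
        supine_start_s=float(data["supine_start_s"]),
        tilt_onset_s=float(data["tilt_onset_s"]),
        recording_end_s=float(data["recording_end_s"]),
        syncope_onset_s=(float(data["syncope_onset_s"]) if data.get("syncope_onset_s") is not None else None),
    )


def write_phase_annotation(annotation: PhaseAnnotation, path: str | Path) -> None:
    data = {
        "supine_start_s": float(annotation.supine_start_s),
        "tilt_onset_s": float(annotation.tilt_onset_s),
        "recording_end_s": float(annotation.recording_end_s),
    }
    if annotation.syncope_onset_s is not None:
        data["syncope_onset_s"] = float(annotation.syncope_onset_s)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


SUMMARY_COLUMNS = (
    "subject",
    "group",
    "phase",
    "signal",
    "mean",
    "sd1",
    "sd2",
    "gi",
    "gi_s",
    "pi",
    "n",
    "n_plus",
    "n_minus",
)


def write_summary_table(rows: Iterable, path: str | Path) -> None:
    """Serialize per-(subject, phase, signal) descriptor bundles to CSV.

    ``rows`` are :class:`~tiltasym.poincare.PoincareSummary` objects (any
    object with the summary fields works).  Raises on an empty collection.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no summaries to write")
    records = []
    for r in rows:
        records.append(
            {
                "subject": r.subject,
                "group": getattr(r.group, "value", r.group),
                "phase": r.phase,
                "signal": r.signal,
                "mean": r.mean,
                "sd1": r.sd1,
                "sd2": r.sd2,
                "gi": r.gi,
                "gi_s": r.gi_s,
                "pi": r.pi,
                "n": r.n,
                "n_plus": r.n_plus,
                "n_minus": r.n_minus,
            }
        )
    pd.DataFrame.from_records(records, columns=list(SUMMARY_COLUMNS)).to_csv(path, index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary columns {missing}")
    return df
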