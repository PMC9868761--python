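"""Poincaré-plot geometry and variability/asymmetry descriptors.

The Poincaré plot of a beat-to-beat signal s is the scatter of consecutive
pairs (s_i, s_{i+1}).  Points above the line of identity (LI, y = x) are
decelerations for RR (the interval lengthened) and pressure rises for BP
signals; points below are accelerations / pressure falls.

Descriptors
-----------
SD1   spread across the LI: sqrt(mean of squared perpendicular distances
      D⊥ = (y − x)/√2 over the n points off the LI).
SD2   spread along the LI: sqrt(mean of squared parallel distances
      D∥ = ((x − x̄) + (y − ȳ))/√2 from the centroid, over all points).
GI    Guzik's Index: percentage of SD1² contributed by decelerations,
      100 · Σ_{D⊥>0} D⊥² / Σ_{D⊥≠0} D⊥².
GI_S  slow-variability analogue of GI on the parallel distances,
      100 · Σ_{decel} D∥² / Σ D∥² (on-LI points split evenly).
PI    Porta's Index: percentage of off-LI points below the LI,
      100 · n⁻ / (n⁺ + n⁻).

Asymmetry of a segment is declared when GI > 50, PI > 50 or GI_S < 50
(strict inequalities; the boundary is symmetric).

An undefined descriptor (e.g. SD1 of a constant series) is reported as NaN
with a warning, never silently defaulted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .signals import PhaseSegment

__all__ = [
    "PlotGeometry",
    "PoincareSummary",
    "AsymmetryFlags",
    "build_geometry",
    "sd1",
    "sd2",
    "guzik_index",
    "guzik_index_slow",
    "porta_index",
    "summarize_segment",
    "classify_asymmetry",
]

#: Relative tolerance of the on-LI test: |y − x| ≤ tol · max(1, |x|).
#: Device-resolution RR/BP values make an exact tie the common case; the
#: tolerance only absorbs float rounding.
ON_LI_RTOL = 1e-9

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class PlotGeometry:
    """Poincaré-plot points and their signed distances.

    ``d_perp`` is the signed perpendicular offset from the line of identity
    ((y − x)/√2, positive above the LI); ``d_par`` the signed parallel offset
    from the centroid along the LI.  ``on_li`` marks points with y = x up to
    float tolerance.
    """

    x: np.ndarray
    y: np.ndarray
    d_perp: np.ndarray
    d_par: np.ndarray
    on_li: np.ndarray
    centroid: tuple[float, float]

    @property
    def n_points(self) -> int:
        return len(self.x)

    @property
    def n_plus(self) -> int:
        """Points above the LI (decelerations / pressure rises)."""
        return int(np.sum(~self.on_li & (self.d_perp > 0)))

    @property
    def n_minus(self) -> int:
        """Points below the LI (accelerations / pressure falls)."""
        return int(np.sum(~self.on_li & (self.d_perp < 0)))

    @property
    def n_off_li(self) -> int:
        return int(np.sum(~self.on_li))

    @property
    def n_zero(self) -> int:
        return int(np.sum(self.on_li))


def build_geometry(values: np.ndarray, valid: np.ndarray | None = None) -> PlotGeometry:
    """Build the Poincaré plot of a signal, skipping pairs with a masked beat.

    One point per adjacent pair of valid beats; a pair spanning an invalid
    beat contributes nothing.  Raises when no point can be formed.
    """
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(values)
    pair = valid[:-1] & valid[1:]
    x = values[:-1][pair]
    y = values[1:][pair]
    if len(x) < 1:
        raise ValueError("empty plot: no adjacent valid beat pair")
    d_perp = (y - x) / _SQRT2
    cx, cy = float(np.mean(x)), float(np.mean(y))
    d_par = ((x - cx) + (y - cy)) / _SQRT2
    on_li = np.abs(y - x) <= ON_LI_RTOL * np.maximum(1.0, np.abs(x))
    return PlotGeometry(x=x, y=y, d_perp=d_perp, d_par=d_par, on_li=on_li, centroid=(cx, cy))


def sd1(geom: PlotGeometry, denominator: str = "off_li") -> float:
    """Beat-to-beat variability: RMS perpendicular distance from the LI.

    ``denominator='off_li'`` divides by the number of off-LI points (on-LI
    points contribute neither to the numerator nor the count);
    ``'all_points'`` uses the conventional all-points count.
    """
    n = geom.n_off_li if denominator == "off_li" else geom.n_points
    if denominator not in ("off_li", "all_points"):
        raise ValueError("denominator must be 'off_li' or 'all_points'")
    if geom.n_off_li == 0:
        warnings.warn("SD1 undefined: every point lies on the line of identity")
        return float("nan")
    num = float(np.sum(geom.d_perp[~geom.on_li] ** 2))
    return math.sqrt(num / n)


def sd2(geom: PlotGeometry, denominator: str = "off_li") -> float:
    """Slow variability: RMS parallel distance from the centroid.

    On-LI points carry genuine parallel spread and are always included;
    the ``denominator`` switch exists only for signature symmetry with
    :func:`sd1` (both conventions divide by all points here).
    """
    if geom.n_points < 2:
        warnings.warn("SD2 undefined: fewer than 2 plot points")
        return float("nan")
    return math.sqrt(float(np.sum(geom.d_par**2)) / geom.n_points)


def guzik_index(geom: PlotGeometry) -> float:
    """GI: percentage of the squared perpendicular spread due to decelerations."""
    off = ~geom.on_li
    den = float(np.sum(geom.d_perp[off] ** 2))
    if geom.n_off_li == 0 or den == 0.0:
        warnings.warn("GI undefined: no point off the line of identity")
        return float("nan")
    num = float(np.sum(geom.d_perp[off & (geom.d_perp > 0)] ** 2))
    return 100.0 * num / den

def guzik_index_slow(geom: PlotGeometry) -> float:
    """GI_S: deceleration share of the squared parallel spread (SD2²).

    Points on the LI are neither decelerations nor accelerations; their
    parallel contribution is split evenly so the two shares always sum
    to 100%.
    """
    den = float(np.sum(geom.d_par**2))
    if geom.n_points < 2 or den == 0.0:
        warnings.warn("GI_S undefined: no parallel spread")
        return float("nan")
    dec = ~geom.on_li & (geom.d_perp > 0)
    num = float(np.sum(geom.d_par[dec] ** 2)) + 0.5 * float(np.sum(geom.d_par[geom.on_li] ** 2))
    return 100.0 * num / den


def porta_index(geom: PlotGeometry) -> float:
    """PI: percentage of off-LI points below the LI (accelerations)."""
    n = geom.n_off_li
    if n == 0:
        warnings.warn("PI undefined: no point off the line of identity")
        return float("nan")
    return 100.0 * geom.n_minus / n


@dataclass(frozen=True)
class PoincareSummary:
    """Per-(subject, phase, signal) descriptor bundle; NaN marks undefined."""

    subject: str
    group: str
    phase: str
    signal: str
    mean: float
    sd1: float
    sd2: float
    sd1d2: float
    sd2d2: float
    gi: float
    gi_s: float
    pi: float
    n: int
    n_plus: int
    n_minus: int
    n_zero: int


@dataclass(frozen=True)
class AsymmetryFlags:
    """Occurrence indicators; None where the underlying index is undefined."""

    gi_asym: bool | None
    pi_asym: bool | None
    gis_asym: bool | None


def summarize_segment(segment: "PhaseSegment", signal: str, sd_denominator: str = "off_li") -> PoincareSummary:
    """Compute mean + all Poincaré descriptors of one signal in one segment.

    The mean is over valid beats (not plot points).  Undefined descriptors
    propagate as NaN.
    """
    series = segment.series
    values = series.signal(signal)
    valid = series.valid & np.isfinite(values)
    mean = float(np.mean(values[valid])) if valid.any() else float("nan")
    nan = float("nan")
    try:
        geom = build_geometry(values, series.valid)
    except ValueError:
        warnings.warn(f"segment {segment.label}/{signal}: no Poincaré point; descriptors missing")
        return PoincareSummary(
            subject=series.subject_id, group=series.group.value, phase=segment.label, signal=signal,
            mean=mean, sd1=nan, sd2=nan, sd1d2=nan, sd2d2=nan, gi=nan, gi_s=nan, pi=nan,
            n=0, n_plus=0, n_minus=0, n_zero=0,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s1 = sd1(geom, sd_denominator)
        s2 = sd2(geom, sd_denominator)
        gi = guzik_index(geom)
        gis = guzik_index_slow(geom)
        pi = porta_index(geom)
    # companion quantities: SD1d² (deceleration share of SD1²), SD2d² likewise
    sd1d2 = gi / 100.0 * s1 * s1 if math.isfinite(gi) and math.isfinite(s1) else nan
    sd2d2 = gis / 100.0 * s2 * s2 if math.isfinite(gis) and math.isfinite(s2) else nan
    return PoincareSummary(
        subject=series.subject_id, group=series.group.value, phase=segment.label, signal=signal,
        mean=mean, sd1=s1, sd2=s2, sd1d2=sd1d2, sd2d2=sd2d2, gi=gi, gi_s=gis, pi=pi,
        n=geom.n_off_li, n_plus=geom.n_plus, n_minus=geom.n_minus, n_zero=geom.n_zero,
    )


def classify_asymmetry(summary: PoincareSummary) -> AsymmetryFlags:
    """Apply the occurrence criteria GI > 50, PI > 50, GI_S < 50 (strict)."""

    def _flag(value: float, predicate) -> bool | None:
        return None if not math.isfinite(value) else bool(predicate(value))

    return AsymmetryFlags(
        gi_asym=_flag(summary.gi, lambda v: v > 50.0),
        pi_asym=_flag(summary.pi, lambda v: v > 50.0),
        gis_asym=_flag(summary.gi_s, lambda v: v < 50.0),
    )
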