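# Methods

## The analysis

`tiltasym` analyses beat-to-beat recordings from head-up tilt tests (HUTT):
per heartbeat, the RR interval (ms) and systolic/diastolic finger pressure
(mmHg), with pulse pressure PP = sBP − dBP derived. The scientific question
it serves is whether the *asymmetry* of short-term heart-rate and
blood-pressure variability — the unequal contribution of decelerations vs
accelerations, a form of time irreversibility — responds differently to
orthostatic stress in vasovagal-syncope patients (VVS(+)) than in healthy
controls (VVS(−)).

### Poincaré descriptors

For a signal s, the Poincaré plot is the scatter of (s_i, s_{i+1}) over
adjacent valid beats. With D⊥ = (y − x)/√2 the signed perpendicular distance
from the line of identity (LI) and D∥ = ((x − x̄) + (y − ȳ))/√2 the signed
parallel distance from the centroid:

* SD1 = √(Σ D⊥² / n) over the n points off the LI — beat-to-beat variability;
* SD2 = √(Σ D∥² / N) over all N points — slow variability;
* GI = 100 · Σ_{D⊥>0} D⊥² / Σ_{D⊥≠0} D⊥² — deceleration share of SD1²;
* GI_S = 100 · Σ_{decel} D∥² / Σ D∥² — deceleration share of SD2²;
* PI = 100 · n⁻ / (n⁺ + n⁻) — fraction of off-LI points below the LI.

Asymmetry of a segment is declared by the strict criteria GI > 50, PI > 50,
GI_S < 50. For BP signals "deceleration" means pressure rise (y > x).

Numerical choices:

* **SD1 denominator.** The definitional form divides by off-LI points only,
  which differs from the common all-points convention when exact ties occur
  (frequent at device resolution). Both are available via
  `sd_denominator={'off_li','all_points'}`; the off-LI form is the default.
  SD2 always divides by all points — on-LI points carry genuine parallel
  spread.
* **On-LI test.** |y − x| ≤ 1e−9·max(1, |x|), absorbing float rounding only;
  exact ties are the intended common case.
* **GI_S on-LI handling.** On-LI points are neither decelerations nor
  accelerations; their D∥² is split evenly between the two sums so the
  deceleration and acceleration shares always total 100% of SD2².
* **Undefined descriptors** (constant series, no off-LI point) propagate as
  NaN with a warning, never as a 0/50 default, and classification flags
  become `None`.

### Preprocessing and protocol windows

Non-sinus beats are flagged by a quotient filter: beat i is flagged when
RR_i/RR_{i±1} falls strictly outside [0.8, 1.2] (the filter's canonical
band; configurable). The boundary is treated as acceptable (closed
interval). Neighbours are flagged only when their own quotients fail.
Flagged beats are *masked*, not deleted: values are untouched, Poincaré
pairs spanning a masked beat are dropped, and the flagged fraction stays
computable for the exclusion rules.

Subjects are excluded when (strictly) >5% of beats are flagged, >10% of BP
samples are missing, either analysis phase is shorter than 5 min, or — in
the patient arm — syncope occurred <6 min after tilt onset.

Analysis windows (half-open in time): S = 300 s centred in the supine phase
(the protocol says "middle part"; a centred window is the symmetric,
deterministic reading), T = first 300 s of tilt, S1 = 180 s centred in
supine, T1 = first 180 s of tilt, T2 = the 180 s before syncope onset.
T1 and T2 cannot overlap for any analysable subject (syncope ≥ 360 s after
tilt).

### Statistical scheme

All inference is nonparametric, two-sided, α = 0.05 (used for annotation
only, never filtering):

* between groups, per phase/signal/measure: Mann–Whitney U (exact when
  combined n ≤ 25 without ties, else tie-corrected normal approximation);
* within group, S vs T: Wilcoxon signed-rank (zeros dropped, same
  exact/approximate policy, no continuity correction);
* patient arm across S1/T1/T2: Friedman (tie-corrected) with pairwise
  Wilcoxon post-hoc under Holm correction;
* asymmetry occurrence across S1/T1/T2: Cochran Q omnibus with pairwise
  McNemar post-hoc under Holm correction. McNemar defaults to the
  **uncorrected** χ² = (b−c)²/(b+c): this is the variant whose
  Holm-adjusted triple reproduces the published dBP values
  (0.024, 0.068, 0.763) from the printed 2×2 tables; the
  continuity-corrected and exact-binomial variants sit behind
  `mcnemar_variant`.
* Shapiro–Wilk is computed for reporting only.

Correction is applied within each post-hoc family only; no cross-signal or
cross-index multiplicity correction is attempted, matching how such studies
report their tables.

`reconstruct_threeway` rebuilds the 8-cell per-subject occurrence pattern
from three printed pairwise 2×2 tables (7 constraints, one free integer,
scanned for the unique non-negative solution). It exists so the Cochran Q
omnibus can be recomputed from published tables; when subject-level flags
are available the pattern is built directly.

Holm adjustment is implemented directly (step-down with enforced
monotonicity, capped at 1) and cross-checked against
`statsmodels.multipletests` in the test suite; the in-package version avoids
a costly garbage-collection pass that statsmodels performs per call, which
matters in replicate simulations.

## The synthetic cohort

No recordings are distributed, so `tiltasym.synthetic` fabricates cohorts
that exhibit exactly the features the pipeline consumes. It is a
statistical emulator, not a hemodynamic model.

* **AR(1) backbone.** A stationary AR(1) is the minimal process with
  independent control of SD1 and SD2: SD1² = γ₀(1−φ), SD2² = γ₀(1+φ), so
  φ = (SD2²−SD1²)/(SD2²+SD1²). `ar1_from_sd` inverts the pair; round-trip
  recovery is part of the acceptance checks (median error < 3% at 5000
  beats).
* **Asymmetry injection.** Linear Gaussian processes are time-reversible
  (GI → 50), so GI targets are met with two-sided scale-skewed innovations
  (positive side scaled by r, probability 1/(1+r) to keep the mean at zero);
  r is calibrated by bisection on the realised mean GI with a deterministic
  internal Monte Carlo, cached per (target, φ, length) bucket.
* **Blood pressure.** dBP is an AR(1) stream at (sd1_bp, sd2_bp) plus a
  one-beat-lagged fraction (0.3) of the RR innovation, a baroreflex-flavoured
  coupling; sBP = dBP + an independent positive pulse-pressure stream
  (sd1 = 1.3·sd1_bp, sd2 = 0.75·sd2_bp, the typical PP:dBP variability
  ratios). One (sd1_bp, sd2_bp) pair drives both channels. This guarantees
  sBP > dBP and gives PP realistic variability.
* **Artifacts.** Ectopics follow a compensatory-pause model — RR_i·u with
  u ~ U(0.4, 0.6) and the removed time added to RR_{i+1} — so cumulative
  time, and hence segmentation, is untouched. ⌊rate·n⌋ events are placed at
  least 3 beats apart; BP missingness blanks both channels of ⌊rate·n⌋
  beats. Count-based placement keeps default cohorts deterministically
  below the exclusion thresholds.
* **Study conditions.** Default phase templates: controls rest supine 420 s
  then stand 360 s (means 860.5 → 726.4 ms RR, 114.6 → 122.6 mmHg sBP,
  76.1 → 86.7 mmHg dBP; RR SD1 25.34 → 14.47 ms, SD2 64.87 → 63.84 ms);
  patients rest 600 s, tilt 300 s (858.6 → 701 ms, 110.5 → 123.9,
  68.8 → 84.7; SD1 24.53 → 14.33), then a 180 s pre-syncope tail falling
  toward 597 ms RR / 109.6 / 73.0 mmHg with explicit negative drifts, and a
  syncope annotation at tilt + 480 s. GI targets: 47.3 supine / 53 tilt in
  controls, 50.5 / 52 / 52 in patients. Subject heterogeneity: a common RR
  scale factor (σ = 5%, clipped ±15%), a common BP shift (σ = 5 mmHg) plus a
  small PP shift (σ = 2.5 mmHg), and a log-normal SD scale (σ = 0.15),
  shared across phases so phase contrasts are preserved. Default
  artifact_rate = 0.01 and bp_missing_rate = 0.03: with the compensatory
  pause the filter typically flags the ectopic and both neighbours (≈3× the
  injection rate), and defaults must leave every subject analysable.

What the generator does **not** emulate — respiration-driven oscillations,
baroreflex feedback loops, nonstationarity within phases beyond a linear
drift, menstrual-cycle modulation, measurement-device quantisation. Passing
tests therefore demonstrate that the *pipeline* measures what it claims on
signals with known structure; they say nothing new about the clinical
populations themselves, whose subject-level tables are not reproducible
without the original recordings.

## Problem sizes in tests and acceptance runs

The suite runs desk-scale versions of the stochastic checks: 200 seeds for
GI-calibration checks, 31 seeds × 5000 beats for AR(1) round-trips, 10⁴
random walks of length 300 for the symmetric-null calibration of GI/PI,
10⁴ simulations for McNemar's type-I error, and 100 replicate 10+10-subject
null cohorts for the pipeline-level false-positive rate (accepted band
[0.01, 0.12] at α = 0.05, acknowledging test discreteness at these sample
sizes). These sizes were chosen as the smallest at which the Monte-Carlo
standard errors are comfortably inside the asserted bands.

## Known limitations

* The exact placement of the 5-min supine window within long supine phases
  is a convention (centred); recordings analysed elsewhere with a different
  offset will differ slightly.
* Whether the original analyses included on-LI points in the SD2 denominator
  is unknowable from the published text; the config switch documents the
  ambiguity rather than resolving it.
* `reconstruct_threeway` fails loudly when the three pairwise tables do not
  pin a unique pattern; genuinely non-unique systems exist and are reported
  with the feasible range instead of a guess.
* The GI calibration targets the *mean* realised GI; per-segment realised
  values scatter by several points at 3–5-min lengths, as they do in real
  recordings.
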