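# Methods

This document describes the algorithms, parameter choices and numerical
decisions in `vestib`, in enough detail to reimplement them.

## Conventions

- All angles are degrees, all times seconds, at every API surface.
- Gaze is in normalized screen coordinates: bottom-left `(0, 0)`, top-right
  `(1, 1)`. Head orientation is Euler angles with `(0, 0, 0)` facing the
  screen straight ahead; positive yaw is a rightward turn (clockwise viewed
  from above), positive pitch is upward.
- Sample rate is a property of the data, not of the algorithms: everything
  uses actual timestamps and tolerates jitter. Timestamps must be strictly
  increasing; violations are errors, never silently repaired.
- `ScreenGeometry` defaults model the reference hardware: a 15.6-inch
  1920×1080 laptop viewed from 762 mm. Normalized offsets convert to visual
  angle via `atan(offset_mm / distance)`.

## Head velocity estimation (`vestib.velocity`)

Instantaneous angular velocity is the first difference of head angle over
consecutive samples, timestamped at the interval midpoint. The estimator
then groups the velocities inside a trailing window into **chains**:

1. Only samples with `t_mid` in `(t_now − window, t_now]` are used
   (`window = 0.25 s`).
2. A chain is a left-to-right run of same-sign velocities. One opposite-sign
   sample per chain is tolerated (noise flips single samples); a second
   opposite-sign sample closes the chain and opens a new one. Exact zeros
   carry no direction: they close the chain and belong to none.
3. Chains need at least 2 members; shorter ones are discarded.
4. The reported **direction** is that of the longest chain (ties go to the
   most recent). The reported **speed** is the mean of `|v|` over the members
   of *all* retained chains. If no chain formed, the estimate is `no_chain`.
5. Speed classification against the clinician-set threshold is inclusive:
   exactly at the target speed passes.

Target speeds per axis and preset (deg/s):

| preset  | horizontal | vertical |
|---------|-----------:|---------:|
| slow    | 60         | 45       |
| medium  | 120        | 78       |
| fast    | 180        | 88       |
| fastest | 240        | 95       |

A consequence worth noting: the windowed mean of `|v|` over a sinusoid
evaluated at its velocity peak is attenuated by `sin(ωW)/(ωW)` (`ω = 2πf`,
`W` the window length) — about 10% at 0.5 Hz and 36% at 1 Hz. The estimator
intentionally reports this smoothed quantity, not the instantaneous peak; see
[Known limitations](#known-limitations).

## Gaze-on-target and grace period (`vestib.gaze`)

Target radii are fractions of screen height (`small 0.05`, `medium 0.10`,
`large 0.15`; the medium value anchors the logged ±0.1 on-target band, the
others are configurable stand-ins). Two acceptance regions are supported:
`circle` (default; the x offset is multiplied by the physical aspect ratio so
the region is circular on the screen) and `band` (independent ±radius per
axis, matching raw platform logs). Invalid gaze (eyes closed, tracking lost)
is never on target. Feedback logic applies a 0.5 s grace period: reward
continues until gaze has been off target for longer than the grace interval.

## Exercise engines (`vestib.exercises`)

Sessions are continuous blocks of 30–120 s. Scoring starts one estimator
window (0.25 s) after the first sample so the speed estimate is defined from
the first scored frame, and ends at the first frame at or past the configured
duration. Frame intervals are not truncated at the boundary, so a session
always accrues at least its nominal duration; combined with clipping this
lets a perfectly performed session reach a plant size of exactly 1.0.

- **VORx1 / VORx2** — the plant grows by `dt / duration` over every interval
  in which the eyes are on target (within grace) *and* the head is at or
  above the threshold speed; otherwise it holds (it never shrinks). VORx1
  keeps the target at screen center; VORx2 moves it anti-phase to the head by
  one normalized unit per 30° of head angle (configurable gain), clamped to
  the screen.
- **Gaze shift** — a repetition is a gaze entry into the side target followed
  by the head crossing ±15° toward that side; then the target switches sides.
  The median eye-to-head latency over repetitions is reported.
- **Remembered target** — a trial is: fixate the target, hold the eyes closed
  (gaze invalid) for ≥ 0.3 s, reopen. Damage is `max(0, 1 − error/d_max)`
  with `error` the reopening gaze-to-target distance (aspect-corrected
  screen-height units) and `d_max` three target radii; cumulative damage is
  capped at 1.

Session metrics are time-weighted (each frame weighted by the interval since
the previous frame), so replaying a stored frame log reproduces the live
metrics exactly. Adherence is completed/assigned per week, pooled counts for
the overall figure; values above 100% are permitted and flagged.

## Dynamic visual acuity (`vestib.dva`)

Pacing: one metronome beat is one single-direction head turn, so
`cycle_hz = bpm / 120` and a beat lasts `60 / bpm` seconds.

**Latency-compensated trigger.** The tracker-to-display pipeline is assumed
to lag by a fixed horizon (default 130 ms). At each sample the trigger fits a
least-squares line through the last 5 head-position samples and extrapolates
it to the predicted zero crossing. The optotype may flash only when the head
is within 20° of straight ahead, moving toward center faster than 60 deg/s,
and the predicted crossing lies within the horizon. The flash is scheduled at
`max(t_now, t_cross − horizon)` as soon as that instant falls before the next
sample — scheduling at the predicted instant rather than on a frame boundary
keeps onset timing free of sample-grid quantization. One onset is issued per
crossing; the trigger re-arms after the observed position changes sign.

On a pure sinusoid the compensated onset lands *after* the true crossing by a
tempo-dependent bias: the line fit is centered ~2 samples in the past and the
trajectory is curved, so the extrapolated root is late by approximately
`L − atan(ωL′)/ω` terms that grow with `ω`. Measured on noiseless 60 s
streams: mean |onset − crossing| = 11.1 / 22.2 / 33.3 ms at 60 / 90 / 120 bpm.

**Staircase.** Optotype size starts at 1.0 logMAR and shrinks by 0.1 per
correct response; an incorrect response re-presents the same size; three
consecutive incorrect responses terminate the test with acuity = the smallest
size answered correctly (current + 0.1). A correct answer at the floor (0.0)
terminates with the floor. The static test (SVA) presents at will; the
dynamic test (DVA) presents only at trigger onsets and additionally reports
the smallest size answered correctly per head direction.

## Patient-reported outcomes (`vestib.instruments`)

All item counts, answer domains, weights, bands and grades live in
`data/instruments.json`; scorers are data-driven.

| instrument | scoring | scale | interpretation / MDC |
|---|---|---|---|
| mABC | mean of 16 items on the 0/25/50/75/100 grid | 0–100 | higher = more confident |
| DHI | 25 × yes/sometimes/no = 4/2/0, summed | 0–100 | MDC 18 |
| DRS | single integer | 0–5 | None 0–1, Mild 2, Moderate 3, Severe 4–5; MDC 1 |
| VAS | mark distance on a 10 cm line | 0–10 | dizziness MDC 4.3 cm; differences may be negative |
| mMST | per movement `max(0, Δintensity) +` duration points (<5 s 0; 5–10 s 1; 11–30 s 2; >30 s 3); MSQ = `n_positive × Σscores / 20.48` | ≥ 0 | symptom relief never scores negative |
| SUS | standard scoring × 2.5 | 0–100 | curved grades: A+ ≥ 84.1, A ≥ 80.8, A− ≥ 78.9, B+ ≥ 77.2, B ≥ 74.1, B− ≥ 72.6, C+ ≥ 71.1, C ≥ 65.0, C− ≥ 62.7, D ≥ 51.7, else F |

The digital forms forbid skips, so every scorer requires a complete response
set; validation failures name the offending item.

## Reliability statistics (`vestib.reliability`)

Validity uses Pearson correlations (scipy), banded at `≤ 0.25` little or
none, `< 0.50` low to fair, `< 0.75` moderate to good, `≥ 0.75` strong.
Test-retest reliability uses ICC(2,1) — single-measure absolute agreement
from the two-way random-effects ANOVA mean squares:

```
ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)
```

with the standard F-based confidence interval (Satterthwaite degrees of
freedom for the lower/upper F quantiles). Bands: `< 0.50` poor, `≤ 0.75`
moderate, `≤ 0.90` good, else excellent. Complete cases only; missing values
are an error, never imputed. Minimal-detectable-change flags use strict
inequality (`|Δ| > MDC`).

## Synthetic data (`vestib.synthetic`)

Head motion is a paced sinusoid `θ(t) = A sin(2πft)`; a sinusoid (not a
triangle wave) models paced turning, giving peak velocity `2πfA`. The
reported value at time `t` is the true value at `t − latency` (default
130 ms). Gaze error follows a VOR-gain model: gain `g` leaves a retinal error
`(1 − g)·θ`, projected to normalized screen units. White Gaussian noise is
added to head angles (default SD 0.5°) and gaze coordinates (default SD
0.01) — a stand-in for the real sensor's unpublished noise spectrum. Every
generator takes an explicit seed and is bit-reproducible.

Default amplitudes per tempo place the peak speed at the values observed on
the validation hardware: `{60 bpm: 31.8°, 90: 25.5°, 120: 22.3°}` → ~100,
~120, ~140 deg/s.

The psychophysical observer answers a 4-alternative tumbling-E task with
`P(correct | s) = chance + (1 − chance − lapse)·logistic((s − threshold)/slope)`
and picks uniformly among wrong orientations otherwise. The questionnaire
respondent draws a full PRO set whose expected symptom scores rise
monotonically with a severity parameter in [0, 1] (balance confidence falls);
usability is independent of severity.

Deliberate non-goals: no biomechanical realism (no asymmetric turns, fatigue
or non-sinusoidal velocity profiles), no saccade dynamics, no colored sensor
noise.

## Design decisions

- **Onset scheduling.** Firing the flash at `max(t_now, t_cross − horizon)`
  instead of on the next frame removes ±½-sample quantization from onset
  timing, which matters when validating 10–30 ms biases.
- **Warm-up before scoring.** Starting sessions one estimator window late
  trades 0.25 s of data for a well-defined speed estimate on every scored
  frame, avoiding a `no_chain` transient at session start.
- **Data-driven instruments.** Questionnaire revisions (weights, bands,
  grades) edit `instruments.json`, not code.
- **Deterministic reports.** `report_json` sorts keys, fixes separators and
  rejects NaN, so byte-identical inputs give byte-identical, diffable
  documents.
- **Plain functions over a fit/results object hierarchy.** The package is a
  signal-processing and scoring tool; nothing estimates a model from data
  that would warrant a statsmodels-style `Model.fit() → Results` shape.

## Known limitations

Two properties one might expect of the system are *not* achievable with the
algorithms as defined, and the acceptance suite deliberately keeps the
corresponding assertions failing rather than weakening them:

1. **Windowed speed ≠ instantaneous peak.** At a position zero crossing the
   trailing-window mean of `|v|` equals `2πfA · sin(ωW)/(ωW)`: 90.0%, 78.3%
   and 63.7% of the peak at 0.5, 0.75 and 1.0 Hz (W = 0.25 s). Recovering
   the peak to 5% would require a centered window or a different estimator.
   The unit suite verifies the estimator against this closed-form value
   instead.
2. **Trigger accuracy does not peak at 90 bpm on a sinusoid.** The onset
   error is dominated by line-extrapolation bias, which grows monotonically
   with path curvature (~f²): 11.1 / 22.2 / 33.3 ms at 60 / 90 / 120 bpm
   (noiseless). The middle tempo therefore beats 120 bpm but cannot beat
   60 bpm. On real patients the 60 bpm condition degrades for a reason the
   simulator deliberately excludes — the required head excursion is large
   and uncomfortable, so real motion departs from a sinusoid. The 90 bpm
   onsets do land within ±25 ms of the true crossings, and the qualitative
   earliness ordering (onsets almost never early at higher tempi) holds.
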