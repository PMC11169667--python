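# vestib

Signal processing and scoring toolkit for remotely delivered, gamified
vestibular rehabilitation.

Patients with vestibular hypofunction retrain their gaze stability by turning
the head rapidly while keeping the eyes locked on a target. A home platform
built on a consumer eye-and-head tracker must, in real time and from noisy
data, answer a handful of questions: *which way is the head moving, and fast
enough?* — *are the eyes on the target?* — *when will the head sweep through
straight-ahead, so a test symbol can be flashed at peak head speed despite a
~130 ms tracker-to-display latency?* This package implements that
computational core, plus the digital questionnaires and the statistics used to
validate them:

- **`vestib.streams`** — tracker stream data model (normalized gaze + head
  Euler angles, degrees and seconds everywhere), CSV I/O, visual-angle
  conversion.
- **`vestib.velocity`** — chain-based head direction/speed estimation: runs of
  same-direction instantaneous velocities in a trailing 0.25 s window, with a
  one-sample tolerance for noise-flipped samples.
- **`vestib.gaze`** — target geometry, gaze-on-target tests (circular or
  per-axis band), off-target grace period.
- **`vestib.exercises`** — per-frame engines for the four exercises (VORx1,
  VORx2, gaze shift, remembered target), session metrics, adherence.
- **`vestib.dva`** — static/dynamic visual acuity: latency-compensated
  optotype trigger (line-fit extrapolation of the head trajectory, flash
  scheduled one anticipation horizon before the predicted zero crossing) and a
  descending logMAR staircase.
- **`vestib.instruments`** — patient-reported outcomes: mABC, DHI, DRS,
  symptom VAS, mMST/MSQ, SUS with curved letter grades; all constants in a
  declarative data table.
- **`vestib.synthetic`** — seeded simulators: paced sinusoidal head motion
  with VOR-gain gaze error, reporting latency and sensor noise; scripted
  gaze-shift and remembered-target traces; a logistic psychophysical observer;
  a severity-driven questionnaire respondent.
- **`vestib.reliability` / `vestib.report`** — Pearson validity, ICC(2,1)
  test-retest agreement with F-based CIs, minimal-detectable-change flags, and
  a deterministic summary-report JSON.

## Quick start

Score a simulated VORx1 session end to end:

```python
from vestib import ExerciseConfig, MotionSimParams, run_session
from vestib.synthetic import simulate_vorx_stream

stream = simulate_vorx_stream(
    MotionSimParams(seed=7, amplitude_deg=25.5, cycle_hz=None, bpm=90.0,
                    duration_s=61.0)
)
config = ExerciseConfig(game="vorx1", duration_s=60.0, speed_preset="slow")
frames, metrics = run_session(config, stream)
print(round(metrics.final_plant_size, 3), round(metrics.pct_time_both, 1))
```

```
0.893 89.3
```

The plant grew for 89.3% of the session: the 90 bpm sinusoid dips below the
60 deg/s threshold around each head reversal.

Measure dynamic visual acuity on a simulated patient:

```python
from vestib import MotionSimParams, ObserverParams, TriggerParams, make_observer, run_dva
from vestib.synthetic import DEFAULT_AMPLITUDE_BY_BPM, head_positions, simulate_vorx_stream

stream = simulate_vorx_stream(
    MotionSimParams(seed=3, amplitude_deg=DEFAULT_AMPLITUDE_BY_BPM[90],
                    cycle_hz=None, bpm=90.0, duration_s=120.0)
)
observer = make_observer(ObserverParams(threshold_logmar=0.6, slope_logmar=0.05, seed=12))
result = run_dva(observer, head_positions(stream), TriggerParams(), seed=3)
print(result.acuity_logmar, result.n_trials, result.acuity_by_direction)
```

```
0.5 9 {'leftward': 0.5, 'rightward': 0.6}
```

Score a questionnaire:

```python
from vestib import score_sus

result = score_sus([5, 2, 4, 1, 5, 1, 4, 2, 5, 1])
print(result.value, result.category)
```

```
90.0 A+
```

The same workflows are available from the command line:

```sh
vestib simulate --seed 7 --cycle-hz 0.75 --duration-s 61 --out stream.csv
vestib run-session --config session.json --stream stream.csv --out metrics.json
vestib dva --mode dva --bpm 90 --seed 7
vestib score-pro --in responses.json --out scores.json
vestib reliability --in paired_scores.csv --stat icc
vestib report --sessions s.json --scores p.json --adherence a.json --out report.json
```

## Testing

```sh
python -m pytest -q tests/
```

The suite contains unit and property tests for every module (including
exhaustive equivalence of the chain estimator against an independent
reference, and cross-checks of ICC(2,1) against an effect-decomposition
oracle and against `pingouin`), plus an end-to-end acceptance suite in
`tests/test_acceptance.py`. Two acceptance assertions are expected to fail
and are left failing deliberately; see
[docs/methods.md](docs/methods.md#known-limitations) for the analysis:

- the trailing-window speed estimator cannot recover the sinusoid's peak
  velocity to 5% (its windowed mean is attenuated by `sin(wW)/(wW)`);
- the optotype-onset timing error grows with pacing tempo, so 90 bpm cannot
  beat 60 bpm on a pure sinusoid.

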