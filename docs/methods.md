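# Methods

## Signal model and preprocessing

All trigger policies consume a single preprocessed channel. The raw stream
(rotation angle in degrees, force in grams, or touch-swipe speed; nominal
60 Hz) is processed strictly causally, because the system being simulated
makes its decision at the instant each sample arrives:

1. **Smoothing.** A trailing moving average over 300 ms of data. The kernel
   length adapts to the sampling rate estimated from the timestamps,
   `k = round(0.3 · fs)` (18 samples at 60 Hz). The rate is estimated as the
   reciprocal of the *median* inter-sample interval, which is robust to
   samples dropped by a streaming device. The 300 ms scale matches the time
   a large voluntary movement takes to complete.
2. **Rate of change.** The per-sample gradient of the smoothed signal
   (central finite differences where both neighbours exist, one-sided at the
   edges) averaged over the same trailing 300 ms window, expressed in
   signal-units per second. Sign is preserved: pressing/gripping/clockwise
   positive, releasing/counterclockwise negative.
3. **Noise gating.** A per-exercise *movement minimum* separates movement
   from sensor noise: the mean over at-rest recordings of the recording's
   maximum |rate of change|. Samples at or below it are flagged
   sub-minimum — flagged, not deleted, so the sample clock stays uniform.

Edge handling is a genuine free choice and is resolved as follows: the first
`k−1` outputs of each trailing mean average all samples seen so far (a
growing window), which avoids both look-ahead and zero-padding artifacts.
The consequence is a startup transient in the rate-of-change signal (its
first two windows are computed from barely smoothed samples, so noise is
amplified up to ~20×). Because a rest calibration describes steady-state
noise, `estimate_movement_minimum` ignores samples within two windows of a
recording's start whenever enough samples remain; recordings too short to
have settled are used whole.

## Trigger policies

**Dynamic (rolling percentile).** Each incoming supra-minimum sample is
pushed into a FIFO buffer of capacity 3000 (≈50 s of movement at 60 Hz);
the threshold is the linearly interpolated percentile `p` of the buffer,
recomputed after every push. A trigger fires iff movement has initiated
(at least one supra-minimum sample so far), the sample's magnitude
*strictly* exceeds the threshold (strictness keeps a constant signal from
triggering on itself), the governing buffer holds at least 30 values (a
percentile of a near-empty buffer is meaningless), and at least `min_isi`
seconds (default 5) have passed since the previous trigger. The buffer is
maintained as a FIFO queue plus an incrementally sorted list, so each step
costs O(log n) search instead of a re-sort; the batch runner is an exact
fold of the streaming step and also records the per-sample threshold trace.

Whether sub-minimum samples belong in the buffer is ambiguous in principle;
they are excluded by default (rest samples would deflate the threshold
during long pauses) and admitted with `include_subminimum=True`.

*Directionality.* Four modes:

* `both` (default): one buffer of magnitudes |x|; either direction may
  trigger. This reads "the movement magnitude is in the top 5% of recent
  samples" literally.
* `positive_only` / `negative_only`: one buffer built only from samples of
  that sign, compared in that sign's direction — the one-sided threshold
  curve a rotation exercise with a preferred direction produces.
* `bidirectional`: two disjoint sign-keyed buffers with independent
  thresholds, for asymmetric deficits where the weak direction would
  otherwise never win against the strong one.

**Static (fixed threshold).** Threshold `m · MM` for multiplier `m` and
movement minimum `MM > 0` (a zero `MM` is rejected: the threshold would
degenerate to zero and fire on noise). During a sustained supra-threshold
plateau, the policy re-fires each time the ISI gate reopens (`every_isi`,
the default) or once per upward crossing (`per_crossing`); the plateau
behaviour is not observable from the outside and both readings are exposed.

**Periodic.** Triggers at `start + k·T`, `k = 1, 2, …`, up to and including
the session end (a 60 s session at `T = 12 s` fires 5 times — 5
stims/minute). A tick landing within one sample period of the nominal end is
kept.

## Metrics

* **Rate**: triggers per minute of session time.
* **Percent-of-max selectivity**: per trigger, |paired value| over the
  session's maximum |rate of change|, ×100; aggregated per session by the
  median (the cohort statistics reported elsewhere are medians with IQR, so
  the per-session aggregate follows the same convention).
* **Recent-percentile selectivity**: the mid-rank percentile (count below
  plus half the ties, over the buffer size) of the trigger's magnitude
  within the buffer snapshot recorded at the trigger. By construction a
  dynamic trigger strictly exceeds the interpolated `p`-th percentile of its
  snapshot; under the mid-rank convention that bounds the rank below by
  `p − 45/n` for a buffer of `n` values — fractionally below `p` only while
  the buffer is still small early in a session.
* **ISI statistics**: successive trigger-time differences; mean ± SEM over
  sessions with ≥2 triggers.
* **Periodic baseline**: for every phase offset of a 12 s periodic grid
  (offsets step at the sampling period across one interval), the max
  |value| within ±1 s of each grid point is averaged over grid points, then
  over offsets. One number per session; the improvement metric reports each
  trigger's windowed paired peak relative to it (mean ± SEM). The
  all-offsets average is one literal reading of "every possible 2-second
  sample"; `n_offsets=1` gives the single-phase variant.
* **Cohort summaries**: median/IQR, mean/SEM, Tukey whiskers
  (Q1 − 1.5·IQR, Q3 + 1.5·IQR) and a distribution-free 90% median CI from
  binomial order statistics. Paired/unpaired two-tailed t-tests with guards
  for degenerate (zero-variance) inputs; significance threshold 0.05.

Sessions with zero triggers contribute a rate of 0 but no selectivity value:
"never stimulated" and "stimulated on poor movements" are different failure
modes and are not conflated.

## Synthetic sessions

`generate_session` emulates what the policies assume about rehabilitation
movement: bursts of voluntary movement separated by rest, person- and
exercise-dependent amplitude, slow drift, sensor noise.

| parameter | default | why |
|---|---|---|
| `duration` | 120 s | between the 30 s minimum and multi-minute game sessions |
| `sampling_rate` | 60 Hz | controller streaming rate |
| `burst_rate` | 40 /min | game-controlling cadence (~1 movement / 1.5 s); places dynamic p95 in its ~5 triggers/min operating regime |
| burst kernel | raised cosine, mean full width 0.7 s (SD 0.2, floor 0.2 s) | ~300 ms out-stroke plus return; smooth single-peaked rate of change |
| amplitude | lognormal, median 30 units, σ = 0.5 | right-skewed movement sizes, occasional large excursions |
| `rest_fraction` | 0.25 | 1–3 rest blocks covering a quarter of the session |
| `drift` | −0.2 | 20% amplitude decline from fatigue |
| `asymmetry` | 1.0 | balanced directions; < 1 emulates an impaired direction |
| `noise_sd` | 0.5 units | sensor noise; yields a movement minimum ≈ 1.9 units/s |

Burst signs split 50/50 (always positive for touch speed, which is a speed).
All randomness flows from one integer seed through
`numpy.random.default_rng`; annotations (onset, peak time, peak amplitude,
sign) are emitted so tests can attribute triggers to bursts exactly.

The simulated therapist (`simulate_manual_triggers`) presses on movement
peaks at ≥50% of the running session maximum, misses 20% of them, reacts
with latency 0.6 ± 0.2 s, and respects the 5 s ISI — a deliberately simple
observer model whose purpose is direction, not magnitude: the dynamic
policy should pair at least as large peaks as a human watcher.

What passing on synthetic cohorts shows: the policies' construction-level
guarantees (ISI gate, percentile exceedance, fold equivalence) and the
qualitative ordering of the policies' selectivity. What it does not show:
clinical movement statistics — absolute selectivity percentages on real
patient signals depend on signal families this generator does not model.

## Numerical choices

* Percentile convention: linear interpolation at fractional index
  `(n−1)·p/100`, identical in the streaming buffer and the batch primitive
  (and to `numpy.percentile`'s default).
* Strict `>` tie rule at both thresholds.
* Periodic end-point tolerance 1e−9 s, trigger-to-signal pairing tolerance
  one sample period.
* Timestamps serialize with 6 decimal places (sub-sample at 60 Hz and
  byte-reproducible logs).
* t-tests and SEM via scipy.stats; everything threshold-related is computed
  in this package.

## Problem sizes

Cohort-level tests and the acceptance script use 20–100 sessions of 120 s
at 60 Hz (7200 samples each); construction-level checks use sessions of a
few hundred to 50 000 samples. These sizes give stable medians and
Monte-Carlo fractions (±0.5 percentage points on the stationary 5%
exceedance check) while a full run stays in the seconds-to-minutes range.

## Known limitations

* The generator's burst model is stationary within a session apart from the
  drift envelope; no tremor, no game-phase structure, no multi-channel
  coupling.
* The `both` directionality mode thresholds magnitudes, so a strongly
  asymmetric signal can leave the weak direction untriggered — that is what
  `bidirectional` is for, and the choice between them is the user's.
* The movement-initiation latch can be set off by the preprocessing startup
  transient when a session begins with pure noise; in practice the
  30-sample minimum buffer fill keeps spurious early triggers rare.
* The therapist model is not fitted to human reaction data; only ordering
  conclusions should be drawn from it.
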