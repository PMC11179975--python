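"""Seeded synthetic rehabilitation sessions and simulated therapist triggers.

No patient movement data is deposited with the study this package models, so
every policy and metric is exercised on synthetic sessions that reproduce the
statistical structure the trigger policies assume: bursty voluntary movements
(raised-cosine excursions a few hundred milliseconds to ~1.5 s long) separated
by rest blocks, lognormally distributed burst amplitudes that differ between
people and exercises, a slow fatigue drift over the session, additive sensor
noise, and optional directional asymmetry for impaired movement directions.

What the generator deliberately does NOT emulate: game-specific signal
idiosyncrasies, tremor spectra, multi-dimensional sensor fusion, or
biomechanically realistic limb dynamics.  Conclusions drawn from synthetic
cohorts are about the trigger policies' construction, not about clinical
movement statistics.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical configs give bit-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_core import RawSignal, RocSignal
from .triggering import DEFAULT_MIN_ISI_S, TriggerEvent

_SIGNAL_KINDS = {
    "rotation": ("rotation_x", "degrees"),
    "force": ("force", "grams"),
    "touch_speed": ("touch_speed", "px_per_s"),
}


@dataclass
class SynthConfig:
    """Session-generation settings.

    Defaults describe a typical game-controlling upper-limb exercise: a
    2-minute session at 60 Hz with ~40 movements per minute (one movement
    every 1.5 s, the cadence of steering- or swiping-style gameplay),
    raised-cosine bursts of ~0.7 s (large movements take about 300 ms, plus
    the return stroke), lognormal peak amplitudes with median 30 sensor
    units, a quarter of the session spent resting, a 20% amplitude decline
    from fatigue, and a 0.5-unit sensor-noise floor.  This cadence places
    the dynamic policy in its intended operating regime of roughly five
    triggers per minute at the 95th percentile.
    """

    seed: int = 0
    duration: float = 120.0
    sampling_rate: float = 60.0
    signal_kind: str = "rotation"
    burst_rate: float = 40.0  # bursts per minute of non-rest time
    burst_amplitude_log_mean: float = math.log(30.0)
    burst_amplitude_log_sd: float = 0.5
    burst_duration_mean: float = 0.7  # full width, seconds
    burst_duration_sd: float = 0.2
    rest_fraction: float = 0.25
    drift: float = -0.2  # fractional amplitude change across the session
    asymmetry: float = 1.0  # negative-direction amplitude ratio (1 = balanced)
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.duration < 30:
            raise ValueError("duration must be >= 30 s (minimum session length)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal_kind not in _SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {sorted(_SIGNAL_KINDS)}")
        if not 0 <= self.rest_fraction < 1:
            raise ValueError("rest_fraction must be in [0, 1)")
        if self.asymmetry <= 0:
            raise ValueError("asymmetry must be positive")
        if self.burst_rate < 0 or self.noise_sd < 0:
            raise ValueError("burst_rate and noise_sd must be >= 0")
        if self.burst_duration_mean <= 0:
            raise ValueError("burst_duration_mean must be positive")

    @property
    def channel_label(self) -> str:
        return _SIGNAL_KINDS[self.signal_kind][0]

    @property
    def units(self) -> str:
        return _SIGNAL_KINDS[self.signal_kind][1]


@dataclass
class TherapistModel:
    """A button-pressing observer watching for large movements.

    The therapist triggers on movement peaks above ``detection_fraction_of_max``
    of the largest movement seen so far, missing a fraction of them outright,
    reacting with a normally distributed latency, and never pressing twice
    within ``min_isi`` seconds.
    """

    detection_fraction_of_max: float = 0.5
    reaction_latency_mean: float = 0.6
    reaction_latency_sd: float = 0.2
    min_isi: float = DEFAULT_MIN_ISI_S
    miss_probability: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.detection_fraction_of_max <= 1:
            raise ValueError("detection_fraction_of_max must be in [0, 1]")
        if self.min_isi < 0:
            raise ValueError("min_isi must be >= 0")
        if not 0 <= self.miss_probability <= 1:
            raise ValueError("miss_probability must be in [0, 1]")


def _rest_mask(rng: np.random.Generator, t: np.ndarray, config: SynthConfig) -> np.ndarray:
    """Boolean mask of rest blocks covering ~rest_fraction of the session."""
    mask = np.zeros(t.size, dtype=bool)
    total_rest = config.rest_fraction * config.duration
    if total_rest <= 0:
        return mask
    n_blocks = int(rng.integers(1, 4))
    lengths = rng.dirichlet(np.ones(n_blocks)) * total_rest
    for length in lengths:
        start = rng.uniform(0, config.duration - length)
        mask |= (t >= start) & (t < start + length)
    return mask


def generate_session(config: SynthConfig) -> tuple[RawSignal, pd.DataFrame]:
    """One synthetic session plus ground-truth burst annotations.

    The signal is a sum of raised-cosine burst kernels (Poisson onsets
    thinned by the rest mask, lognormal amplitudes, signs split evenly with
    the negative side scaled by ``asymmetry``), multiplied by a linear
    fatigue-drift envelope, plus white Gaussian sensor noise.

    Annotations carry one row per burst: ``onset_s``, ``peak_s``,
    ``amplitude`` (envelope-adjusted peak height) and ``sign`` — so tests can
    score trigger-to-burst attribution without peak-finding heuristics.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sampling_rate
    t = np.arange(0.0, config.duration, dt)
    rest = _rest_mask(rng, t, config)

    # homogeneous Poisson onsets over the session, thinned where at rest
    expected = config.burst_rate / 60.0 * config.duration
    n_candidates = int(rng.poisson(expected))
    onsets = np.sort(rng.uniform(0, config.duration, n_candidates))
    envelope = 1.0 + config.drift * (t / config.duration)

    signal = np.zeros_like(t)
    rows = []
    for onset in onsets:
        idx = min(int(onset / dt), t.size - 1)
        if rest[idx]:
            continue
        width = max(0.2, rng.normal(config.burst_duration_mean, config.burst_duration_sd))
        amp = rng.lognormal(config.burst_amplitude_log_mean, config.burst_amplitude_log_sd)
        sign = 1.0
        if config.signal_kind != "touch_speed" and rng.random() < 0.5:
            sign = -1.0
            amp *= config.asymmetry
        lo = int(np.searchsorted(t, onset))
        hi = int(np.searchsorted(t, onset + width))
        if hi <= lo:
            continue
        phase = (t[lo:hi] - onset) / width
        signal[lo:hi] += sign * amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        peak_s = onset + width / 2.0
        env_at_peak = 1.0 + config.drift * (peak_s / config.duration)
        rows.append(
            {
                "onset_s": onset,
                "peak_s": peak_s,
                "amplitude": amp * env_at_peak,
                "sign": sign,
            }
        )

    signal *= envelope
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, t.size)
    raw = RawSignal(
        timestamps=t,
        values=signal,
        channel_label=config.channel_label,
        sampling_rate=config.sampling_rate,
    )
    annotations = pd.DataFrame(rows, columns=["onset_s", "peak_s", "amplitude", "sign"])
    return raw, annotations


def generate_rest_recording(config: SynthConfig) -> RawSignal:
    """Noise-only recording (controller held with the arm at rest), used to
    calibrate the per-exercise movement minimum."""
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sampling_rate
    t = np.arange(0.0, config.duration, dt)
    values = (
        rng.normal(0.0, config.noise_sd, t.size)
        if config.noise_sd > 0
        else np.zeros_like(t)
    )
    return RawSignal(
        timestamps=t,
        values=values,
        channel_label=config.channel_label,
        sampling_rate=config.sampling_rate,
    )


def simulate_manual_triggers(
    roc: RocSignal, model: TherapistModel, seed: int
) -> list[TriggerEvent]:
    """Simulate a therapist pressing the stimulation button.

    Movement peaks are local maxima of |rate of change|; a peak is
    detectable when it reaches ``detection_fraction_of_max`` of the largest
    magnitude observed so far in the session (the observer's sense of "a
    large movement for this patient").  Detected peaks are missed with
    ``miss_probability``; accepted ones produce a trigger at
    ``peak time + latency``, suppressed by the minimum ISI.
    """
    from scipy.signal import find_peaks

    rng = np.random.default_rng(seed)
    mag = np.abs(roc.values)
    if len(roc) < 3:
        return []
    fs = 1.0 / float(np.median(np.diff(roc.timestamps)))
    peaks, _ = find_peaks(mag, distance=max(1, int(0.3 * fs)))
    running_max = np.maximum.accumulate(mag)
    events: list[TriggerEvent] = []
    last: float | None = None
    for i in peaks:
        if mag[i] < model.detection_fraction_of_max * running_max[i]:
            continue
        if rng.random() < model.miss_probability:
            continue
        latency = max(0.0, rng.normal(model.reaction_latency_mean, model.reaction_latency_sd))
        t_trig = float(roc.timestamps[i]) + latency
        if t_trig > float(roc.timestamps[-1]):
            continue
        if last is not None and t_trig - last < model.min_isi:
            continue
        events.append(
            TriggerEvent(
                time=t_trig,
                algorithm="manual",
                threshold_at_trigger=None,
                direction="n/a",
            )
        )
        last = t_trig
    return events
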