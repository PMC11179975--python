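"""Preprocessing of raw movement-sensor streams into gated rate-of-change signals.

Rehabilitation controllers stream a single movement dimension (rotation angle
in degrees, force in grams, or touch-swipe speed) at a nominal 60 Hz.  All
trigger policies consume the same derived signal: the raw stream is smoothed
with a causal moving average, differentiated, and the per-sample gradient is
averaged over a trailing window, yielding a signed rate of change in sensor
units per second.  A per-exercise "movement minimum" — the noise floor measured
while the limb is at rest — gates out sub-movement activity.

All windows are trailing (causal): the system this emulates runs in real time,
so no operation may look ahead of the current sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DIRECTIONALITY_MODES = ("both", "positive_only", "negative_only", "bidirectional")

#: Default smoothing / gradient window, chosen because large rehabilitative
#: movements take roughly 300 ms to complete.
DEFAULT_WINDOW_MS = 300.0

#: Nominal controller sampling rate in Hz.
NOMINAL_RATE_HZ = 60.0


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class RawSignal:
    """A time-stamped single-channel sensor stream.

    Parameters
    ----------
    timestamps : array-like
        Sample times in seconds, strictly increasing.
    values : array-like
        Sensor readings in native units (degrees, grams, ...).
    channel_label : str
        Name of the sensor dimension this stream came from.
    sampling_rate : float
        Nominal sampling rate in Hz. A warning is issued if the rate
        estimated from the timestamps deviates from it by more than 20%.
    """

    timestamps: np.ndarray
    values: np.ndarray
    channel_label: str = "signal"
    sampling_rate: float = NOMINAL_RATE_HZ

    def __post_init__(self) -> None:
        self.timestamps = _as_float_array(self.timestamps, "timestamps")
        self.values = _as_float_array(self.values, "values")
        if len(self.timestamps) != len(self.values):
            raise ValueError(
                f"timestamps ({len(self.timestamps)}) and values "
                f"({len(self.values)}) differ in length"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(f"timestamps must be strictly increasing (row {i + 1})")
            est = estimate_sampling_rate(self.timestamps)
            if abs(est - self.sampling_rate) > 0.2 * self.sampling_rate:
                warnings.warn(
                    f"estimated sampling rate {est:.2f} Hz deviates >20% from "
                    f"nominal {self.sampling_rate:.2f} Hz",
                    stacklevel=3,
                )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Session span in seconds (last minus first timestamp)."""
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class RocSignal:
    """Smoothed, windowed rate-of-change signal in signal-units per second.

    ``supra_minimum`` is filled by :func:`gate_noise`: a boolean flag per
    sample marking activity whose magnitude exceeds the movement minimum.
    Values are never altered by gating; downstream policies decide how to
    use the flag.
    """

    timestamps: np.ndarray
    values: np.ndarray
    window_ms: float = DEFAULT_WINDOW_MS
    source_channel: str = "signal"
    supra_minimum: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.timestamps = _as_float_array(self.timestamps, "timestamps")
        self.values = _as_float_array(self.values, "values")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values differ in length")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if self.supra_minimum is not None:
            self.supra_minimum = np.asarray(self.supra_minimum, dtype=bool)
            if len(self.supra_minimum) != len(self.values):
                raise ValueError("supra_minimum flags differ in length from values")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class ExerciseConfig:
    """Per-exercise settings: channel, noise floor, and directionality."""

    exercise_id: str
    channel_label: str
    movement_minimum: float = 0.0
    directionality: str = "both"
    units: str = ""

    def __post_init__(self) -> None:
        if self.movement_minimum < 0:
            raise ValueError("movement_minimum must be >= 0")
        if self.directionality not in DIRECTIONALITY_MODES:
            raise ValueError(
                f"directionality must be one of {DIRECTIONALITY_MODES}, "
                f"got {self.directionality!r}"
            )


def estimate_sampling_rate(timestamps: np.ndarray) -> float:
    """Sampling rate in Hz from the median inter-sample interval.

    The median is robust to occasional dropped samples from a streaming
    tablet; a mean would be biased by every gap.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) < 2:
        raise ValueError("need at least 2 timestamps to estimate a sampling rate")
    dt = float(np.median(np.diff(timestamps)))
    if dt <= 0:
        raise ValueError("timestamps must be strictly increasing")
    return 1.0 / dt


def select_channel(record: dict[str, RawSignal], config: ExerciseConfig) -> RawSignal:
    """Isolate the one sensor dimension an exercise uses, untouched."""
    try:
        return record[config.channel_label]
    except KeyError:
        available = sorted(record)
        raise KeyError(
            f"channel {config.channel_label!r} not present; "
            f"available channels: {available}"
        ) from None


def kernel_size(window_ms: float, sampling_rate: float) -> int:
    """Moving-average kernel length in samples; at least 1."""
    return max(1, round(window_ms / 1000.0 * sampling_rate))


def _causal_mean(values: np.ndarray, k: int) -> np.ndarray:
    # Trailing mean of the most recent k samples; the first k-1 outputs
    # average all samples seen so far (growing window), so no future data
    # leaks in and there is no startup transient from zero padding.
    n = len(values)
    csum = np.concatenate(([0.0], np.cumsum(values)))
    out = np.empty(n)
    k = min(k, n)
    head = np.arange(1, k)
    out[: k - 1] = csum[head] / head
    tail = np.arange(k - 1, n)
    out[k - 1 :] = (csum[tail + 1] - csum[tail + 1 - k]) / k
    return out


def smooth_signal(raw: RawSignal, window_ms: float = DEFAULT_WINDOW_MS) -> RawSignal:
    """Causal moving-average filter over ``window_ms`` of data.

    The kernel length adapts to the sampling rate estimated from the
    timestamps: ``k = round(window_ms/1000 * rate)``, minimum 1.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if len(raw) == 0:
        raise ValueError("cannot smooth an empty signal")
    if len(raw) == 1:
        return RawSignal(raw.timestamps.copy(), raw.values.copy(),
                         raw.channel_label, raw.sampling_rate)
    rate = estimate_sampling_rate(raw.timestamps)
    k = kernel_size(window_ms, rate)
    return RawSignal(
        raw.timestamps.copy(),
        _causal_mean(raw.values, k),
        raw.channel_label,
        raw.sampling_rate,
    )


def rate_of_change(smoothed: RawSignal, window_ms: float = DEFAULT_WINDOW_MS) -> RocSignal:
    """Windowed mean gradient of the smoothed signal, in units per second.

    The per-sample gradient (central finite differences, one-sided at the
    edges) is averaged over a trailing window of ``window_ms``, producing a
    single signed rate-of-change value per sample: positive for pressing,
    gripping, or clockwise rotation; negative for releasing or
    counterclockwise rotation.
    """
    if len(smoothed) < 2:
        raise ValueError("need at least 2 samples for a rate of change")
    rate = estimate_sampling_rate(smoothed.timestamps)
    grad = np.gradient(smoothed.values, smoothed.timestamps)
    k = kernel_size(window_ms, rate)
    return RocSignal(
        timestamps=smoothed.timestamps.copy(),
        values=_causal_mean(grad, k),
        window_ms=window_ms,
        source_channel=smoothed.channel_label,
    )


def estimate_movement_minimum(rest_recordings: list[RocSignal]) -> float:
    """Noise floor: mean over at-rest recordings of each recording's max |value|.

    The causal smoothing/gradient chain has a startup transient (its first
    windows average very few samples, so noise is barely attenuated there).
    The noise floor describes steady-state sensor noise, so samples within
    two windows of the recording start are ignored whenever the recording is
    long enough to have settled; very short recordings are used whole.
    """
    if not rest_recordings:
        raise ValueError("need at least one rest recording")
    maxima = []
    for rec in rest_recordings:
        if len(rec) == 0:
            raise ValueError("rest recording is empty")
        values = rec.values
        settle = rec.timestamps[0] + 2.0 * rec.window_ms / 1000.0
        settled = values[rec.timestamps >= settle]
        if settled.size:
            values = settled
        maxima.append(float(np.max(np.abs(values))))
    return float(np.mean(maxima))


def gate_noise(roc: RocSignal, movement_minimum: float) -> RocSignal:
    """Flag samples whose |value| strictly exceeds the movement minimum.

    Values are kept intact — gating marks sub-movement noise rather than
    deleting samples, so timestamps stay uniform for the rolling buffer.
    """
    if movement_minimum < 0:
        raise ValueError("movement_minimum must be >= 0")
    return RocSignal(
        timestamps=roc.timestamps.copy(),
        values=roc.values.copy(),
        window_ms=roc.window_ms,
        source_channel=roc.source_channel,
        supra_minimum=np.abs(roc.values) > movement_minimum,
    )


def align_clocks(session_start_times_device_a, event_start_times_device_b) -> float:
    """Mean pairwise clock offset (device B minus device A), in seconds.

    Callers subtract the returned offset from device-B timestamps to bring
    externally logged events (e.g. manual stimulation presses on a phone)
    onto the movement-recording device's clock.
    """
    a = np.asarray(session_start_times_device_a, dtype=float)
    b = np.asarray(event_start_times_device_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both timestamp lists must be non-empty")
    if a.size != b.size:
        raise ValueError(f"paired lists differ in length: {a.size} vs {b.size}")
    return float(np.mean(b - a))


def preprocess(
    raw: RawSignal,
    window_ms: float = DEFAULT_WINDOW_MS,
    movement_minimum: float = 0.0,
) -> RocSignal:
    """Full chain: smooth -> rate of change -> noise gate."""
    return gate_noise(rate_of_change(smooth_signal(raw, window_ms), window_ms),
                      movement_minimum)
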