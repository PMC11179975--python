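"""Stimulation-trigger policies: dynamic rolling-percentile, static, periodic.

Three policies decide when a closed-loop stimulation trigger should fire
while a patient exercises:

* **dynamic** — keeps a FIFO buffer of up to 3000 recent rate-of-change
  samples and recomputes a percentile threshold on every new sample; a sample
  strictly exceeding the threshold fires a trigger (the top-``100-p``% of
  recent movement).
* **static** — a fixed threshold at ``multiplier x movement_minimum``.
* **periodic** — a countdown timer, blind to the signal.

Dynamic and static triggers are gated by a minimum inter-stimulus interval
(default 5 s) and, for the dynamic policy, by movement initiation: nothing
fires before the first supra-minimum sample of the session.

The streaming primitive is :func:`dynamic_step`; :func:`run_dynamic` is an
exact fold of it over a session and additionally records the per-sample
threshold trace.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right, insort
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_core import DIRECTIONALITY_MODES, RocSignal

ALGORITHMS = ("dynamic", "static", "periodic", "manual")

DEFAULT_BUFFER_SIZE = 3000
DEFAULT_MIN_ISI_S = 5.0
DEFAULT_MIN_BUFFER_FILL = 30


@dataclass
class TriggerEvent:
    """One simulated stimulation decision.

    ``paired_value`` is the signed rate-of-change value coincident with the
    trigger (for periodic/manual triggers it is filled in later by pairing
    against a signal).  ``threshold_at_trigger`` is the governing threshold at
    that instant, signed to match the trigger direction; ``None`` for the
    signal-agnostic periodic policy.  ``buffer_snapshot`` (dynamic only, on
    request) is the sorted magnitude buffer the threshold was computed from.
    """

    time: float
    paired_value: float = math.nan
    threshold_at_trigger: float | None = None
    algorithm: str = "dynamic"
    direction: str = "n/a"
    buffer_snapshot: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.direction not in ("positive", "negative", "n/a"):
            raise ValueError("direction must be 'positive', 'negative' or 'n/a'")


@dataclass
class DynamicParams:
    """Settings for the rolling-percentile policy.

    percentile : threshold percentile of recent movement, in (0, 100).
        The study's tested settings were 45, 55, 65, 75, 85 and 95.
    buffer_size : FIFO capacity in samples (3000 ~ 50 s at 60 Hz).
    min_isi : minimum inter-stimulus interval, seconds.
    directionality : which movement directions may trigger and whether one
        or two distributions are maintained (see module docs).
    include_subminimum : admit sub-noise-floor samples into the buffer.
        Off by default: excluded activity would deflate thresholds during
        long rests.
    min_buffer_fill : no triggers until the governing buffer holds this many
        values (a percentile of a near-empty buffer is meaningless).
    """

    percentile: float = 95.0
    buffer_size: int = DEFAULT_BUFFER_SIZE
    min_isi: float = DEFAULT_MIN_ISI_S
    directionality: str = "both"
    include_subminimum: bool = False
    min_buffer_fill: int = DEFAULT_MIN_BUFFER_FILL

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.buffer_size < 2:
            raise ValueError("buffer_size must be >= 2")
        if self.min_isi < 0:
            raise ValueError("min_isi must be >= 0")
        if self.directionality not in DIRECTIONALITY_MODES:
            raise ValueError(f"directionality must be one of {DIRECTIONALITY_MODES}")
        if self.min_buffer_fill < 2:
            raise ValueError("min_buffer_fill must be >= 2")


@dataclass
class StaticParams:
    """Settings for the fixed-threshold policy.

    The threshold is ``multiplier x movement_minimum``; tested multipliers
    were 1, 2, 4, 8, 16 and 32.  ``retrigger`` controls behavior during a
    sustained supra-threshold plateau: ``"every_isi"`` (default) fires again
    each time the ISI gate reopens while the signal stays above threshold;
    ``"per_crossing"`` fires only once per upward crossing.
    """

    multiplier: float = 32.0
    movement_minimum: float = 0.0
    min_isi: float = DEFAULT_MIN_ISI_S
    directionality: str = "both"
    retrigger: str = "every_isi"

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if self.movement_minimum < 0:
            raise ValueError("movement_minimum must be >= 0")
        if self.min_isi < 0:
            raise ValueError("min_isi must be >= 0")
        if self.directionality not in DIRECTIONALITY_MODES:
            raise ValueError(f"directionality must be one of {DIRECTIONALITY_MODES}")
        if self.retrigger not in ("every_isi", "per_crossing"):
            raise ValueError("retrigger must be 'every_isi' or 'per_crossing'")


@dataclass
class PeriodicParams:
    """Settings for the countdown policy; tested intervals were 6, 6.67,
    7.5, 10, 12 and 15 seconds."""

    interval: float = 12.0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")


def percentile_threshold(buffer_values, percentile: float) -> float:
    """Linearly interpolated order statistic of ``buffer_values``.

    Sorts the values and interpolates at fractional index
    ``(n - 1) * percentile / 100`` — the same convention the streaming
    buffer uses, so batch and streaming thresholds agree exactly.
    """
    values = sorted(float(v) for v in buffer_values)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a percentile threshold")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    return _sorted_percentile(values, percentile)


def _sorted_percentile(sorted_values, percentile: float) -> float:
    idx = (len(sorted_values) - 1) * percentile / 100.0
    lo = int(math.floor(idx))
    frac = idx - lo
    if frac == 0.0:
        return float(sorted_values[lo])
    return float(sorted_values[lo] + frac * (sorted_values[lo + 1] - sorted_values[lo]))


class _RollingBuffer:
    """Bounded FIFO of floats with an incrementally maintained sort order.

    Eviction follows arrival order while percentile queries read the sorted
    view, so each streaming step costs O(log n) search plus an O(n) memmove
    instead of a full re-sort.
    """

    __slots__ = ("capacity", "_fifo", "_sorted")

    def __init__(self, capacity: int):
        self.capacity = capacity
        self._fifo: deque[float] = deque()
        self._sorted: list[float] = []

    def __len__(self) -> int:
        return len(self._fifo)

    def push(self, value: float) -> None:
        if len(self._fifo) == self.capacity:
            oldest = self._fifo.popleft()
            del self._sorted[bisect_left(self._sorted, oldest)]
        self._fifo.append(value)
        insort(self._sorted, value)

    def percentile(self, q: float) -> float:
        return _sorted_percentile(self._sorted, q)

    def snapshot(self) -> np.ndarray:
        """Sorted copy of current contents."""
        return np.asarray(self._sorted, dtype=float)

    def rank_of(self, value: float) -> float:
        """Mid-rank percentile of ``value`` within the buffer, in [0, 100]."""
        below = bisect_left(self._sorted, value)
        equal = bisect_right(self._sorted, value) - below
        return 100.0 * (below + 0.5 * equal) / len(self._sorted)


@dataclass
class DynamicState:
    """Streaming state of the dynamic policy.

    In ``bidirectional`` mode two sign-keyed buffers hold positive-direction
    and negative-direction magnitudes separately; all other modes use only
    ``buffer``.  ``movement_initiated`` latches at the first supra-minimum
    sample and never reverts within a session.
    """

    params: DynamicParams
    buffer: _RollingBuffer = field(init=False)
    buffer_negative: _RollingBuffer | None = field(init=False)
    last_trigger_time: float | None = None
    movement_initiated: bool = False
    threshold_pos: float = math.nan
    threshold_neg: float = math.nan
    _last_time: float = field(default=-math.inf, repr=False)

    def __post_init__(self) -> None:
        self.buffer = _RollingBuffer(self.params.buffer_size)
        self.buffer_negative = (
            _RollingBuffer(self.params.buffer_size)
            if self.params.directionality == "bidirectional"
            else None
        )


def dynamic_step(
    state: DynamicState,
    sample: tuple[float, float, bool],
    params: DynamicParams | None = None,
    record_snapshot: bool = False,
) -> tuple[DynamicState, TriggerEvent | None]:
    """Advance the dynamic policy by one preprocessed sample.

    The sample is ``(time_s, rate_of_change_value, supra_minimum_flag)``.
    It is appended to the governing buffer first (evicting the oldest at
    capacity), the threshold is recomputed, and a trigger fires iff movement
    has initiated, the value strictly exceeds the threshold in an allowed
    direction, and the ISI gate is open.  ``state`` is updated in place and
    returned for convenience.
    """
    params = params or state.params
    t, v, supra = float(sample[0]), float(sample[1]), bool(sample[2])
    if t <= state._last_time:
        raise ValueError(f"out-of-order timestamp {t} after {state._last_time}")
    state._last_time = t
    if supra and not state.movement_initiated:
        state.movement_initiated = True

    mode = params.directionality
    target: _RollingBuffer | None = None   # buffer governing this sample
    compare = abs(v)                       # magnitude compared to its threshold
    if supra or params.include_subminimum:
        if mode == "both":
            target = state.buffer
            target.push(abs(v))
        elif mode == "positive_only":
            if v > 0:
                target = state.buffer
                target.push(v)
        elif mode == "negative_only":
            if v < 0:
                target = state.buffer
                target.push(-v)
        else:  # bidirectional: disjoint sign-keyed distributions
            if v > 0:
                target = state.buffer
                target.push(v)
            elif v < 0:
                target = state.buffer_negative
                target.push(-v)

    # refresh the published thresholds
    if len(state.buffer) >= 2:
        thr = state.buffer.percentile(params.percentile)
        if mode == "negative_only":
            state.threshold_neg = -thr
        else:
            state.threshold_pos = thr
            if mode == "both":
                state.threshold_neg = -thr
    if state.buffer_negative is not None and len(state.buffer_negative) >= 2:
        state.threshold_neg = -state.buffer_negative.percentile(params.percentile)

    event = None
    direction_ok = (
        mode == "both"
        or (mode == "positive_only" and v > 0)
        or (mode == "negative_only" and v < 0)
        or mode == "bidirectional"
    )
    if (
        state.movement_initiated
        and supra
        and direction_ok
        and target is not None
        and len(target) >= max(params.min_buffer_fill, 2)
    ):
        thr_mag = target.percentile(params.percentile)
        isi_open = (
            state.last_trigger_time is None
            or t - state.last_trigger_time >= params.min_isi
        )
        if compare > thr_mag and isi_open:
            direction = "positive" if v >= 0 else "negative"
            event = TriggerEvent(
                time=t,
                paired_value=v,
                threshold_at_trigger=thr_mag if v >= 0 else -thr_mag,
                algorithm="dynamic",
                direction=direction,
                buffer_snapshot=target.snapshot() if record_snapshot else None,
            )
            state.last_trigger_time = t
    return state, event


def run_dynamic(
    roc: RocSignal,
    params: DynamicParams,
    record_snapshots: bool = False,
) -> tuple[list[TriggerEvent], dict[str, np.ndarray]]:
    """Run the dynamic policy over a whole gated session.

    Exactly equivalent to folding :func:`dynamic_step` over the stream.
    Returns the trigger events and the per-sample threshold trace
    ``{"time_s", "threshold_pos", "threshold_neg"}`` (NaN where a threshold
    is undefined) — the adaptive green curve of the policy's working view.
    """
    if len(roc) == 0:
        raise ValueError("cannot run the dynamic policy on an empty signal")
    supra = roc.supra_minimum
    if supra is None:
        supra = np.ones(len(roc), dtype=bool)
    state = DynamicState(params)
    events: list[TriggerEvent] = []
    n = len(roc)
    thr_pos = np.full(n, math.nan)
    thr_neg = np.full(n, math.nan)
    for i in range(n):
        _, event = dynamic_step(
            state,
            (roc.timestamps[i], roc.values[i], supra[i]),
            params,
            record_snapshot=record_snapshots,
        )
        thr_pos[i] = state.threshold_pos
        thr_neg[i] = state.threshold_neg
        if event is not None:
            events.append(event)
    trace = {
        "time_s": roc.timestamps.copy(),
        "threshold_pos": thr_pos,
        "threshold_neg": thr_neg,
    }
    return events, trace


def run_static(roc: RocSignal, params: StaticParams) -> list[TriggerEvent]:
    """Run the fixed-threshold policy over a session.

    The threshold is ``multiplier x movement_minimum``; a zero movement
    minimum is rejected because the threshold would degenerate to zero and
    fire on noise.
    """
    if len(roc) == 0:
        raise ValueError("cannot run the static policy on an empty signal")
    if params.movement_minimum <= 0:
        raise ValueError(
            "movement_minimum must be positive: a multiplier-based threshold "
            "degenerates to 0 otherwise"
        )
    thr = params.multiplier * params.movement_minimum
    v = roc.values
    mode = params.directionality
    if mode == "positive_only":
        above = v > thr
    elif mode == "negative_only":
        above = v < -thr
    else:  # both / bidirectional: a single magnitude threshold either way
        above = np.abs(v) > thr
    events: list[TriggerEvent] = []
    last: float | None = None
    candidates = np.flatnonzero(above)
    for i in candidates:
        t = float(roc.timestamps[i])
        if params.retrigger == "per_crossing" and i > 0 and above[i - 1]:
            continue
        if last is not None and t - last < params.min_isi:
            continue
        val = float(v[i])
        events.append(
            TriggerEvent(
                time=t,
                paired_value=val,
                threshold_at_trigger=thr if val >= 0 else -thr,
                algorithm="static",
                direction="positive" if val >= 0 else "negative",
            )
        )
        last = t
    return events


def run_periodic(
    session_span: tuple[float, float], params: PeriodicParams
) -> list[TriggerEvent]:
    """Fire at ``start + k*interval`` for k = 1, 2, ... up to and including
    the session end.  Paired movement values are filled in later by the
    metrics layer when a signal is supplied."""
    start, end = float(session_span[0]), float(session_span[1])
    if end <= start:
        raise ValueError("session span must have end > start")
    # small tolerance so an endpoint landing exactly on a tick is included
    n_ticks = int(math.floor((end - start) / params.interval + 1e-9))
    return [
        TriggerEvent(
            time=start + k * params.interval,
            algorithm="periodic",
            threshold_at_trigger=None,
            direction="n/a",
        )
        for k in range(1, n_ticks + 1)
    ]


def replace_event(event: TriggerEvent, **changes) -> TriggerEvent:
    """Dataclass-style copy-with-changes for trigger events."""
    return replace(event, **changes)
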