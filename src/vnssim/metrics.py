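"""Evaluation metrics for trigger policies: rate, selectivity, intervals.

Policies are compared on three axes:

* **triggering rate** — triggers per minute of session time (the therapy
  target is about 5/min, i.e. one stimulation every 12 s);
* **selectivity** — how large the movements paired with triggers are, either
  as a percent of the session's maximum movement or as a percentile rank
  within the policy's own recent-movement buffer;
* **inter-stimulus intervals** — whether a policy can hold a therapeutic
  cadence.

A session's paired peak sizes are normalized against a *periodic baseline*:
the average windowed peak around a 12-second periodic grid, averaged over all
phase offsets of the grid, which represents what a movement-blind policy
would have paired on that same session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .signal_core import RocSignal, estimate_sampling_rate
from .triggering import TriggerEvent, replace_event


@dataclass
class SessionMetrics:
    """Per-session summary feeding cohort comparisons."""

    session_id: str
    algorithm: str
    n_triggers: int
    duration_s: float
    triggers_per_minute: float
    selectivity_pct_of_max: float  # NaN when no triggers
    selectivity_recent_percentile: float  # NaN unless dynamic w/ snapshots
    isi_values: list[float]


@dataclass
class CohortSummary:
    """Median/IQR, mean/SEM and Tukey whiskers over a cohort of values.

    ``whisker_low``/``whisker_high`` follow the boxplot rule Q1 - 1.5*IQR
    and Q3 + 1.5*IQR.  ``median_ci90`` is a distribution-free 90% confidence
    interval for the median from binomial order statistics (the quantity a
    notched boxplot displays).
    """

    median: float
    iqr: float
    q1: float
    q3: float
    mean: float
    sem: float
    whisker_low: float
    whisker_high: float
    median_ci90: tuple[float, float]
    n: int


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    test: str  # "paired_t" or "unpaired_t"
    tails: int = 2

    def __post_init__(self) -> None:
        if self.test not in ("paired_t", "unpaired_t"):
            raise ValueError("test must be 'paired_t' or 'unpaired_t'")


def triggering_rate(triggers: list[TriggerEvent], duration: float) -> float:
    """Triggers per minute: count / (duration in minutes)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(triggers) / (duration / 60.0)


def pair_triggers_with_signal(
    triggers: list[TriggerEvent],
    roc: RocSignal,
    pairing_window: float = 0.0,
) -> list[TriggerEvent]:
    """Fill each trigger's ``paired_value`` from the signal.

    With ``pairing_window == 0`` the value at the nearest sample is used;
    otherwise the signed value of largest magnitude within
    ``+/- pairing_window`` seconds (a trigger landing near a movement peak is
    credited with that peak).
    """
    if len(roc) == 0:
        raise ValueError("cannot pair against an empty signal")
    ts = roc.timestamps
    # a trigger may land up to one sample period past the recorded samples
    # (e.g. a periodic tick at the nominal session end)
    tol = float(np.median(np.diff(ts))) if len(ts) > 1 else 1e-9
    out = []
    for ev in triggers:
        if ev.time < ts[0] - tol or ev.time > ts[-1] + tol:
            raise ValueError(f"trigger at {ev.time} s lies outside the signal span")
        i = int(np.searchsorted(ts, ev.time))
        if i >= len(ts) or (i > 0 and ev.time - ts[i - 1] <= ts[i] - ev.time):
            i -= 1
        if pairing_window > 0:
            lo = int(np.searchsorted(ts, ev.time - pairing_window, side="left"))
            hi = int(np.searchsorted(ts, ev.time + pairing_window, side="right"))
            seg = roc.values[lo:hi]
            value = float(seg[np.argmax(np.abs(seg))])
        else:
            value = float(roc.values[i])
        out.append(replace_event(ev, paired_value=value))
    return out


def selectivity_pct_of_max(
    paired_triggers: list[TriggerEvent], roc: RocSignal
) -> tuple[float, np.ndarray]:
    """Paired-movement size as percent of the session's maximum movement.

    Per trigger: ``|paired_value| / max(|signal|) * 100``.  The session value
    is the median across triggers.  Returns ``(session_value, per_trigger)``.
    """
    if not paired_triggers:
        raise ValueError("need at least one trigger")
    max_abs = float(np.max(np.abs(roc.values)))
    if max_abs <= 0:
        raise ValueError("signal maximum is zero; percent-of-max is undefined")
    per = np.array(
        [100.0 * abs(ev.paired_value) / max_abs for ev in paired_triggers]
    )
    if np.any(np.isnan(per)):
        raise ValueError("triggers must be paired with the signal first")
    return float(np.median(per)), per


def selectivity_recent_percentile(
    triggers: list[TriggerEvent],
) -> tuple[float, np.ndarray]:
    """Percentile rank of each trigger's movement within its buffer snapshot.

    Requires a dynamic run recorded with ``record_snapshots=True``.  The rank
    is the mid-rank convention (count below plus half the ties, over the
    buffer size); the session value is the median across triggers.
    """
    if not triggers:
        raise ValueError("need at least one trigger")
    ranks = []
    for ev in triggers:
        snap = ev.buffer_snapshot
        if snap is None:
            raise ValueError(
                "trigger has no buffer snapshot; run the dynamic policy with "
                "record_snapshots=True"
            )
        ranks.append(percentile_rank(snap, abs(ev.paired_value)))
    per = np.asarray(ranks)
    return float(np.median(per)), per


def percentile_rank(values: np.ndarray, score: float) -> float:
    """Mid-rank percentile of ``score`` within ``values``, in [0, 100]."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    below = int(np.count_nonzero(values < score))
    equal = int(np.count_nonzero(values == score))
    return 100.0 * (below + 0.5 * equal) / values.size


def isi_stats(triggers: list[TriggerEvent]) -> tuple[float, float, np.ndarray]:
    """Inter-stimulus intervals: successive trigger-time differences.

    Returns ``(mean, sem, intervals)``; with fewer than two triggers the
    interval list is empty and mean/sem are NaN.
    """
    times = np.array(sorted(ev.time for ev in triggers))
    if times.size < 2:
        return math.nan, math.nan, np.empty(0)
    intervals = np.diff(times)
    mean = float(np.mean(intervals))
    sem = float(stats.sem(intervals)) if intervals.size > 1 else math.nan
    return mean, sem, intervals


def periodic_baseline_peak(
    roc: RocSignal,
    grid_interval: float = 12.0,
    peak_window: float = 1.0,
    n_offsets: int | None = None,
) -> float:
    """Average windowed peak around a periodic grid, over all grid phases.

    For each phase offset of a ``grid_interval``-second periodic grid, the
    maximum |value| within ``+/- peak_window`` seconds of every grid point is
    averaged; the result is then averaged across offsets.  Offsets step at
    the sampling period by default (``n_offsets=None``); pass ``n_offsets=1``
    for the single-phase variant anchored at the session start.

    This is the per-session normalization baseline: the paired-peak size a
    movement-blind periodic policy would achieve on this signal.
    """
    if len(roc) < 2:
        raise ValueError("signal too short")
    if roc.duration <= grid_interval:
        raise ValueError("session must be longer than grid_interval")
    fs = estimate_sampling_rate(roc.timestamps)
    half = max(0, int(round(peak_window * fs)))
    # windowed_max[i] = max |value| within +/- peak_window of sample i
    windowed_max = ndimage.maximum_filter1d(
        np.abs(roc.values), size=2 * half + 1, mode="nearest"
    )
    step_samples = int(round(grid_interval * fs))
    n = len(roc)
    if n_offsets is None:
        offsets = np.arange(min(step_samples, n))
    else:
        if n_offsets < 1:
            raise ValueError("n_offsets must be >= 1")
        offsets = np.unique(
            np.linspace(0, min(step_samples, n) - 1, n_offsets).round().astype(int)
        )
    per_offset = [float(np.mean(windowed_max[off::step_samples])) for off in offsets]
    return float(np.mean(per_offset))


def percent_improvement_over_baseline(
    paired_triggers: list[TriggerEvent], baseline: float
) -> tuple[float, float, np.ndarray]:
    """Per-trigger paired-peak size relative to the periodic baseline.

    ``(|paired_value| - baseline) / baseline * 100`` per trigger; returns
    ``(mean, sem, per_trigger)``.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if not paired_triggers:
        raise ValueError("need at least one trigger")
    per = np.array(
        [100.0 * (abs(ev.paired_value) - baseline) / baseline for ev in paired_triggers]
    )
    if np.any(np.isnan(per)):
        raise ValueError("triggers must be paired with the signal first")
    mean = float(np.mean(per))
    sem = float(stats.sem(per)) if per.size > 1 else math.nan
    return mean, sem, per


def _median_ci90(sorted_values: np.ndarray) -> tuple[float, float]:
    # Distribution-free CI from binomial order statistics; falls back to the
    # extremes when n is too small for 90% coverage.
    n = sorted_values.size
    if n < 2:
        v = float(sorted_values[0])
        return (v, v)
    lo_idx = stats.binom.ppf(0.05, n, 0.5)
    lo = int(max(lo_idx - 1, 0))
    hi = int(min(n - lo - 1, n - 1))
    return float(sorted_values[lo]), float(sorted_values[hi])


def summarize_cohort(values) -> CohortSummary:
    """Median/IQR, mean/SEM, Tukey whiskers and a 90% median CI."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    if np.any(np.isnan(arr)):
        raise ValueError("values contain NaN; filter before summarizing")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    sem = float(stats.sem(arr)) if arr.size > 1 else 0.0
    return CohortSummary(
        median=float(np.median(arr)),
        iqr=float(iqr),
        q1=float(q1),
        q3=float(q3),
        mean=float(np.mean(arr)),
        sem=sem,
        whisker_low=float(q1 - 1.5 * iqr),
        whisker_high=float(q3 + 1.5 * iqr),
        median_ci90=_median_ci90(np.sort(arr)),
        n=int(arr.size),
    )


def compare(values_a, values_b, paired: bool) -> ComparisonResult:
    """Two-tailed t-test between cohorts (paired or unpaired).

    Degenerate inputs are guarded: identical paired groups give t = 0,
    p = 1; a constant nonzero paired difference has zero variance and is
    rejected rather than reported as infinitely significant.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length groups")
        diffs = a - b
        if np.all(diffs == 0):
            return ComparisonResult(statistic=0.0, p_value=1.0, test="paired_t")
        if np.std(diffs) == 0:
            raise ValueError(
                "paired differences are constant and nonzero; "
                "t-statistic is undefined"
            )
        res = stats.ttest_rel(a, b)
        return ComparisonResult(
            statistic=float(res.statistic), p_value=float(res.pvalue), test="paired_t"
        )
    if np.std(a) == 0 and np.std(b) == 0:
        if a[0] == b[0]:
            return ComparisonResult(statistic=0.0, p_value=1.0, test="unpaired_t")
        raise ValueError("both groups are constant; t-statistic is undefined")
    res = stats.ttest_ind(a, b)
    return ComparisonResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), test="unpaired_t"
    )


def session_metrics(
    session_id: str,
    triggers: list[TriggerEvent],
    roc: RocSignal,
    algorithm: str,
) -> SessionMetrics:
    """Assemble the per-session record used in cohort reports.

    Sessions without triggers report a rate of 0 and NaN selectivity (they
    are excluded from selectivity summaries, not counted as zero quality).
    """
    duration = roc.duration
    rate = triggering_rate(triggers, duration) if duration > 0 else 0.0
    sel_max = math.nan
    sel_pct = math.nan
    if triggers and not any(math.isnan(ev.paired_value) for ev in triggers):
        sel_max, _ = selectivity_pct_of_max(triggers, roc)
        if all(ev.buffer_snapshot is not None for ev in triggers):
            sel_pct, _ = selectivity_recent_percentile(triggers)
    _, _, intervals = isi_stats(triggers)
    return SessionMetrics(
        session_id=session_id,
        algorithm=algorithm,
        n_triggers=len(triggers),
        duration_s=duration,
        triggers_per_minute=rate,
        selectivity_pct_of_max=sel_max,
        selectivity_recent_percentile=sel_pct,
        isi_values=[float(x) for x in intervals],
    )
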