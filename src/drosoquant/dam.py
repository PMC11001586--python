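"""Sleep architecture from Drosophila Activity Monitor (DAM) data.

The TriKinetics DAM system records infrared beam crossings per fly in
1-min bins.  Fly sleep is defined behaviorally as any run of uninterrupted
inactivity (zero counts) lasting at least 5 consecutive minutes; runs
shorter than the minimum contribute no sleep.  This module parses monitor
files, detects sleep bouts, computes per-day architecture metrics
(total sleep, bout number, mean bout duration, waking activity, day/night
split on a 12:12 light:dark cycle), bins sleep into time courses, excludes
dead flies, and produces control-subtracted sleep-loss summaries with
SEM propagated in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
DEFAULT_MIN_BOUT = 5
DEFAULT_DEATH_WINDOW = 1440

__all__ = [
    "ActivityTrace",
    "SleepBout",
    "DailySleepMetrics",
    "SleepLossSummary",
    "DamParseError",
    "DamFormatError",
    "read_dam_monitor",
    "write_dam_monitor",
    "detect_bouts",
    "sleep_flags",
    "daily_metrics",
    "summarize_days",
    "sleep_timecourse",
    "exclude_dead",
    "subtract_control",
]


class DamParseError(ValueError):
    """A monitor-file row could not be parsed (names the offending line)."""


class DamFormatError(ValueError):
    """The monitor file violates the DAM dialect (timestamps, emptiness)."""


@dataclass
class ActivityTrace:
    """One fly's per-minute activity counts on a Zeitgeber time grid.

    Parameters
    ----------
    fly_id : str
        Channel or fly label.
    counts : ndarray of int
        Beam-break counts, one per minute, all >= 0.
    start_zt : int
        Minutes after lights-on (ZT0) at which the trace starts;
        0 <= start_zt < 1440.
    lights_on_min, lights_off_min : int
        Minute-of-day marks of the 12:12 light:dark schedule inside each
        1440-min day (ZT0 convention: lights on at 0, off at 720).
    alive_through : int, optional
        Index of the last analyzable minute (defaults to the last minute).
    """

    fly_id: str
    counts: np.ndarray
    start_zt: int = 0
    lights_on_min: int = 0
    lights_off_min: int = 720
    alive_through: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)
        if not 0 <= self.start_zt < MINUTES_PER_DAY:
            raise ValueError("start_zt must lie in [0, 1440)")
        if self.alive_through is None:
            self.alive_through = self.counts.size - 1

    def __len__(self) -> int:
        return self.counts.size

    def zt_of(self, index: int) -> int:
        """Zeitgeber minute-of-day of trace index ``index``."""
        return (self.start_zt + index) % MINUTES_PER_DAY


@dataclass(frozen=True)
class SleepBout:
    """A maximal run of >= ``min_bout`` zero-count minutes."""

    start_min: int
    duration_min: int

    @property
    def end_min(self) -> int:
        """Exclusive end index."""
        return self.start_min + self.duration_min


@dataclass
class DailySleepMetrics:
    day_index: int
    total_sleep_min: int
    n_bouts: int
    mean_bout_min: float | None
    waking_activity: float | None
    day_sleep_min: int
    night_sleep_min: int


@dataclass
class SleepLossSummary:
    """Experimental-minus-control-mean sleep loss with propagated SEM."""

    per_fly_loss: np.ndarray
    group_mean_loss: float
    propagated_sem: float
    raw_exp: np.ndarray = field(repr=False, default=None)
    raw_ctrl: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Monitor-file I/O (standard TriKinetics dialect: tab-separated, columns
# record-index, date, time, status, 6 device fields, 32 channel counts).
# ---------------------------------------------------------------------------

_N_META_COLS = 10
_N_CHANNELS = 32


def read_dam_monitor(
    path,
    channel_map: Sequence[str] | None = None,
    start_zt: int = 0,
) -> list[ActivityTrace]:
    """Parse a TriKinetics monitor file into 32 :class:`ActivityTrace`.

    Rows must be tab-delimited, chronological, 1 min apart, with status
    code 1 (data OK).  Leading/trailing non-OK rows are dropped; an
    interior non-OK row or a timestamp gap raises :class:`DamFormatError`.
    """
    rows: list[tuple[int, pd.Timestamp, int, list[int]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != _N_META_COLS + _N_CHANNELS:
                raise DamParseError(
                    f"line {lineno}: expected {_N_META_COLS + _N_CHANNELS} "
                    f"tab-separated fields, found {len(parts)}"
                )
            try:
                status = int(parts[3])
                stamp = pd.to_datetime(
                    f"{parts[1]} {parts[2]}", format="%d %b %y %H:%M:%S"
                )
                counts = [int(v) for v in parts[_N_META_COLS:]]
            except (ValueError, TypeError) as exc:
                raise DamParseError(f"line {lineno}: {exc}") from exc
            if any(c < 0 for c in counts):
                raise DamParseError(f"line {lineno}: negative count")
            rows.append((lineno, stamp, status, counts))

    if not rows:
        raise DamFormatError("monitor file contains no data rows")

    # drop non-OK rows only at the edges; interior ones break the 1-min grid
    while rows and rows[0][2] != 1:
        rows.pop(0)
    while rows and rows[-1][2] != 1:
        rows.pop()
    if not rows:
        raise DamFormatError("monitor file contains no status-OK rows")
    for lineno, _, status, _ in rows:
        if status != 1:
            raise DamFormatError(
                f"line {lineno}: non-OK status {status} inside recording"
            )

    stamps = pd.Series([r[1] for r in rows])
    deltas = stamps.diff().dropna()
    bad = deltas[deltas != pd.Timedelta(minutes=1)]
    if len(bad):
        pos = bad.index[0]
        raise DamFormatError(
            f"line {rows[pos][0]}: timestamps must advance by exactly 1 min "
            f"(found {deltas.iloc[pos - 1]})"
        )

    matrix = np.array([r[3] for r in rows], dtype=np.int64)
    labels = (
        list(channel_map)
        if channel_map is not None
        else [f"ch{i + 1:02d}" for i in range(_N_CHANNELS)]
    )
    if len(labels) != _N_CHANNELS:
        raise ValueError(f"channel_map must provide {_N_CHANNELS} labels")
    return [
        ActivityTrace(fly_id=labels[j], counts=matrix[:, j], start_zt=start_zt)
        for j in range(_N_CHANNELS)
    ]


def write_dam_monitor(
    counts_matrix: np.ndarray,
    path,
    start: str | pd.Timestamp = "2024-01-01 00:00:00",
) -> None:
    """Write a (minutes x <=32 channels) count matrix as a monitor file."""
    counts_matrix = np.asarray(counts_matrix, dtype=np.int64)
    if counts_matrix.ndim != 2 or counts_matrix.shape[1] > _N_CHANNELS:
        raise ValueError("counts_matrix must be (n_minutes, <=32)")
    n_min, n_ch = counts_matrix.shape
    full = np.zeros((n_min, _N_CHANNELS), dtype=np.int64)
    full[:, :n_ch] = counts_matrix
    t0 = pd.Timestamp(start)
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(n_min):
            stamp = t0 + pd.Timedelta(minutes=i)
            meta = [
                str(i + 1),
                stamp.strftime("%d %b %y"),
                stamp.strftime("%H:%M:%S"),
                "1",
            ] + ["0"] * 6
            fh.write("\t".join(meta + [str(v) for v in full[i]]) + "\n")


# ---------------------------------------------------------------------------
# Bout detection and metrics
# ---------------------------------------------------------------------------


def detect_bouts(
    trace: ActivityTrace, min_bout: int = DEFAULT_MIN_BOUT
) -> list[SleepBout]:
    """Maximal runs of zero-count minutes lasting >= ``min_bout`` min."""
    if min_bout < 1:
        raise ValueError("min_bout must be >= 1")
    counts = trace.counts
    if counts.size == 0:
        raise ValueError("empty trace")
    inactive = counts == 0
    padded = np.concatenate(([False], inactive, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [
        SleepBout(start_min=int(s), duration_min=int(e - s))
        for s, e in zip(starts, ends)
        if e - s >= min_bout
    ]


def sleep_flags(
    trace: ActivityTrace, min_bout: int = DEFAULT_MIN_BOUT
) -> np.ndarray:
    """Boolean per-minute vector: True where the minute is inside a bout."""
    flags = np.zeros(len(trace), dtype=bool)
    for bout in detect_bouts(trace, min_bout):
        flags[bout.start_min : bout.end_min] = True
    return flags


def _day_slices(trace: ActivityTrace) -> list[tuple[int, int]]:
    """(start, end) index pairs of complete ZT days within the trace."""
    first_zt0 = (MINUTES_PER_DAY - trace.start_zt) % MINUTES_PER_DAY
    slices = []
    start = first_zt0
    while start + MINUTES_PER_DAY <= len(trace):
        slices.append((start, start + MINUTES_PER_DAY))
        start += MINUTES_PER_DAY
    return slices


def daily_metrics(
    trace: ActivityTrace, min_bout: int = DEFAULT_MIN_BOUT
) -> list[DailySleepMetrics]:
    """Per-day sleep architecture for each complete ZT0-aligned day.

    Bouts spanning a ZT0 boundary are split at the boundary for the
    per-day minute totals but assigned whole (by their start minute) for
    bout counts and mean duration, so mean_bout * n_bouts recovers the
    unclipped bout minutes of that day.
    """
    days = _day_slices(trace)
    if not days:
        raise ValueError("trace does not span one full day from a ZT0 boundary")
    bouts = detect_bouts(trace, min_bout)
    flags = np.zeros(len(trace), dtype=bool)
    for bout in bouts:
        flags[bout.start_min : bout.end_min] = True

    out = []
    for day_idx, (lo, hi) in enumerate(days):
        day_flags = flags[lo:hi]
        total = int(day_flags.sum())
        day_bouts = [b for b in bouts if lo <= b.start_min < hi]
        n_bouts = len(day_bouts)
        mean_bout = (
            float(np.mean([b.duration_min for b in day_bouts]))
            if n_bouts
            else None
        )
        zts = (trace.start_zt + np.arange(lo, hi)) % MINUTES_PER_DAY
        lights_on = (zts >= trace.lights_on_min) & (zts < trace.lights_off_min)
        day_sleep = int(day_flags[lights_on].sum())
        night_sleep = total - day_sleep
        awake = ~day_flags
        n_awake = int(awake.sum())
        waking = (
            float(trace.counts[lo:hi][awake].sum() / n_awake)
            if n_awake
            else None
        )
        out.append(
            DailySleepMetrics(
                day_index=day_idx,
                total_sleep_min=total,
                n_bouts=n_bouts,
                mean_bout_min=mean_bout,
                waking_activity=waking,
                day_sleep_min=day_sleep,
                night_sleep_min=night_sleep,
            )
        )
    return out


def summarize_days(
    metrics: Sequence[DailySleepMetrics], exclude_first: bool = True
) -> dict[str, float | None]:
    """Mean of each metric across days, dropping day 1 for acclimation.

    With a single day and ``exclude_first``, that day is used (nothing to
    acclimate against).
    """
    use = list(metrics)
    if exclude_first and len(use) > 1:
        use = use[1:]
    if not use:
        raise ValueError("no days to summarize")

    def _mean(attr: str) -> float | None:
        vals = [getattr(m, attr) for m in use]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return {
        "total_sleep_min": _mean("total_sleep_min"),
        "n_bouts": _mean("n_bouts"),
        "mean_bout_min": _mean("mean_bout_min"),
        "waking_activity": _mean("waking_activity"),
        "day_sleep_min": _mean("day_sleep_min"),
        "night_sleep_min": _mean("night_sleep_min"),
    }


def sleep_timecourse(
    traces: Iterable[ActivityTrace],
    bin_min: int = 30,
    min_bout: int = DEFAULT_MIN_BOUT,
) -> pd.DataFrame:
    """Binned group sleep time course (mean +/- SEM min asleep per bin).

    All traces must share ``start_zt`` and length, and ``bin_min`` must
    divide 1440.  Returns one row per bin with columns ``bin_start_min``
    (index into the trace), ``zt_min``, ``mean_sleep_min``, ``sem_sleep_min``
    and the per-fly matrix is available via the ``per_fly`` attribute
    (``DataFrame.attrs``).
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces")
    if MINUTES_PER_DAY % bin_min != 0:
        raise ValueError("bin_min must divide 1440")
    n = len(traces[0])
    zt0 = traces[0].start_zt
    for t in traces[1:]:
        if len(t) != n or t.start_zt != zt0:
            raise ValueError("traces are not aligned to a common ZT grid")
    n_bins = n // bin_min
    if n_bins == 0:
        raise ValueError("trace shorter than one bin")
    usable = n_bins * bin_min
    per_fly = np.array(
        [
            sleep_flags(t, min_bout)[:usable]
            .reshape(n_bins, bin_min)
            .sum(axis=1)
            for t in traces
        ],
        dtype=float,
    )
    mean = per_fly.mean(axis=0)
    if len(traces) > 1:
        sem = per_fly.std(axis=0, ddof=1) / math.sqrt(len(traces))
    else:
        sem = np.zeros(n_bins)
    starts = np.arange(n_bins) * bin_min
    df = pd.DataFrame(
        {
            "bin_start_min": starts,
            "zt_min": (zt0 + starts) % MINUTES_PER_DAY,
            "mean_sleep_min": mean,
            "sem_sleep_min": sem,
        }
    )
    df.attrs["per_fly"] = per_fly
    return df


def exclude_dead(
    traces: Iterable[ActivityTrace],
    death_window: int = DEFAULT_DEATH_WINDOW,
) -> tuple[list[ActivityTrace], list[ActivityTrace], pd.DataFrame]:
    """Partition flies into (kept, excluded) by terminal inactivity.

    A fly is scored dead when its counts are all zero from some minute
    through the end of the trace and that terminal span is at least
    ``death_window`` minutes (default one full day).  Returns the two
    partitions plus an exclusion log with the last-activity minute.
    """
    kept: list[ActivityTrace] = []
    excluded: list[ActivityTrace] = []
    log_rows = []
    for t in traces:
        nz = np.flatnonzero(t.counts)
        last_active = int(nz[-1]) if nz.size else -1
        terminal_zero = len(t) - 1 - last_active
        dead = terminal_zero >= death_window
        (excluded if dead else kept).append(t)
        log_rows.append(
            {
                "fly_id": t.fly_id,
                "last_activity_min": last_active,
                "terminal_zero_min": terminal_zero,
                "excluded": dead,
            }
        )
    return kept, excluded, pd.DataFrame(log_rows)


def subtract_control(
    exp_values: Sequence[float], ctrl_values: Sequence[float]
) -> SleepLossSummary:
    """Per-fly sleep loss relative to the control-group mean.

    Each experimental fly's value minus the control mean; SEMs of the two
    groups combine in quadrature (variance of x_i - mean(ctrl) under
    independence).  Statistics downstream run on the retained raw groups,
    never on the subtracted values.
    """
    exp = np.asarray(exp_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if exp.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    loss = exp - ctrl.mean()

    def _sem(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0

    return SleepLossSummary(
        per_fly_loss=loss,
        group_mean_loss=float(loss.mean()),
        propagated_sem=math.hypot(_sem(exp), _sem(ctrl)),
        raw_exp=exp,
        raw_ctrl=ctrl,
    )
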