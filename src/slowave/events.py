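"""Slow-wave event detection from MPF time courses, and event metrics.

A run of m consecutive sub-threshold windows (2-s windows, 1-s stride)
covers m+1 seconds of signal, so the "at least 5 consecutive seconds"
criterion corresponds to m >= 4 windows.  The comparison is strict
(mpf < threshold) and undefined (NaN) windows break runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spectral import MPFSeries

DEFAULT_THRESHOLD_HZ = 6.0
DEFAULT_MIN_DURATION_S = 5.0
DEFAULT_SWEEP_HZ = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


@dataclass(frozen=True)
class PSWEvent:
    """One detected slow-wave episode in one area."""

    subject_id: str
    area_id: int
    start_s: float
    end_s: float
    mean_mpf_hz: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_pswe(
    series: MPFSeries,
    threshold_hz: float = DEFAULT_THRESHOLD_HZ,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
) -> list[PSWEvent]:
    """Maximal runs of windows with MPF strictly below the threshold.

    A run of windows starting at t0 and ending at t1 spans
    [t0, t1 + window_s]; runs whose span is at least ``min_duration_s``
    become events.  Events truncated by the recording edges still count
    if their span meets the minimum.
    """
    lo, hi = series.band
    if not lo < threshold_hz < hi:
        raise ValidationError(
            f"threshold {threshold_hz} Hz outside the MPF band ({lo}, {hi})"
        )
    if min_duration_s <= 0:
        raise ValidationError("min_duration_s must be > 0")
    mask = np.isfinite(series.mpf_hz) & (series.mpf_hz < threshold_hz)
    events: list[PSWEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for i0, i1 in zip(edges[::2], edges[1::2]):  # [i0, i1) run of True
        start = float(series.times_s[i0])
        end = float(series.times_s[i1 - 1] + series.window_s)
        if end - start >= min_duration_s - 1e-9:
            events.append(
                PSWEvent(
                    subject_id=series.subject_id,
                    area_id=series.area_id,
                    start_s=start,
                    end_s=end,
                    mean_mpf_hz=float(series.mpf_hz[i0:i1].mean()),
                )
            )
    return events


def events_per_minute(events: Sequence[PSWEvent], analyzed_duration_s: float) -> float:
    if analyzed_duration_s <= 0:
        raise ValidationError("analyzed_duration_s must be > 0")
    return len(events) / (analyzed_duration_s / 60.0)


def _check_disjoint(events: Sequence[PSWEvent]) -> None:
    by_area: dict[int, list[PSWEvent]] = {}
    for ev in events:
        by_area.setdefault(ev.area_id, []).append(ev)
    for area, evs in by_area.items():
        evs = sorted(evs, key=lambda e: e.start_s)
        for a, b in zip(evs, evs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValidationError(
                    f"overlapping events in area {area}: "
                    f"[{a.start_s}, {a.end_s}] and [{b.start_s}, {b.end_s}]"
                )


def percent_time_in_pswe(
    events: Sequence[PSWEvent], analyzed_duration_s: float
) -> float:
    """Percent of analyzed time covered by (per-area disjoint) events.

    Intended for the events of a single area; see
    :func:`subject_percent_time` for the per-subject aggregate.
    """
    if analyzed_duration_s <= 0:
        raise ValidationError("analyzed_duration_s must be > 0")
    _check_disjoint(events)
    for ev in events:
        if ev.start_s < -1e-9 or ev.end_s > analyzed_duration_s + 1e-9:
            raise ValidationError(
                f"event [{ev.start_s}, {ev.end_s}] outside [0, {analyzed_duration_s}]"
            )
    covered = sum(ev.duration_s for ev in events)
    return 100.0 * covered / analyzed_duration_s


def subject_percent_time(
    events: Sequence[PSWEvent],
    analyzed_duration_s: float,
    area_ids: Iterable[int] = range(1, 10),
    aggregate: str = "mean",
) -> float:
    """Subject-level percent time in a PSWE state.

    ``aggregate="mean"`` (default) averages the per-area percentages;
    ``aggregate="union"`` measures the union of event intervals across
    areas.
    """
    area_ids = list(area_ids)
    if aggregate == "mean":
        per_area = [
            percent_time_in_pswe([e for e in events if e.area_id == a], analyzed_duration_s)
            for a in area_ids
        ]
        return float(np.mean(per_area)) if per_area else 0.0
    if aggregate == "union":
        _check_disjoint(events)
        ivals = sorted((e.start_s, e.end_s) for e in events if e.area_id in area_ids)
        covered, cur_start, cur_end = 0.0, None, None
        for s, e in ivals:
            if cur_end is None or s > cur_end:
                if cur_end is not None:
                    covered += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        if cur_end is not None:
            covered += cur_end - cur_start
        return 100.0 * covered / analyzed_duration_s
    raise ValidationError(f"unknown aggregate {aggregate!r}")


def threshold_sweep(
    series: MPFSeries,
    thresholds: Sequence[float] = DEFAULT_SWEEP_HZ,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
) -> pd.DataFrame:
    """Re-run detection at each threshold; one row per threshold.

    Columns: threshold_hz, n_events, events_per_min, pct_time.  Percent
    time is non-decreasing in the threshold; the event count need not be
    (adjacent runs merge as the threshold rises).
    """
    duration = float(series.times_s[-1] + series.window_s) if series.times_s.size else 0.0
    rows = []
    for thr in thresholds:
        if thr <= series.band[0]:
            # MPF >= fmin by construction, so nothing can be sub-threshold
            events: list[PSWEvent] = []
        else:
            events = detect_pswe(series, threshold_hz=thr, min_duration_s=min_duration_s)
        rows.append(
            {
                "threshold_hz": float(thr),
                "n_events": len(events),
                "events_per_min": events_per_minute(events, duration),
                "pct_time": percent_time_in_pswe(events, duration),
            }
        )
    return pd.DataFrame(rows)


def events_to_frame(events: Sequence[PSWEvent]) -> pd.DataFrame:
    cols = ["subject_id", "area_id", "start_s", "end_s", "duration_s", "mean_mpf_hz"]
    rows = [
        (e.subject_id, e.area_id, e.start_s, e.end_s, e.duration_s, e.mean_mpf_hz)
        for e in events
    ]
    return pd.DataFrame(rows, columns=cols)
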