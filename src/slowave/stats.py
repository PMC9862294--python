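"""Per-subject pipeline driver and cohort-level statistics.

Group comparisons use per-area Kruskal-Wallis omnibus tests followed, when
the omnibus p is below alpha, by unadjusted pairwise rank-sum tests (an
LSD-style policy, tagged as such in every result row).  A linear
mixed-model route is deliberately not provided.  p-values use the usual
large-sample approximations throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import events as ev
from . import preprocess as pp
from . import regions as rg
from . import spectral as sp
from .errors import ValidationError
from .recording import Recording

AREA_IDS = tuple(range(1, 10))


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter of the per-subject pipeline, with the source
    study's values as defaults (1-95 Hz pass, 45-55 Hz stop, 2 s / 1 s
    windows, MPF < 6 Hz for >= 5 s, sweep 2-8 Hz)."""

    bandpass: pp.FilterSpec | None = pp.BANDPASS_DEFAULT
    bandstop: pp.FilterSpec | None = pp.BANDSTOP_DEFAULT
    exclude: tuple[str, ...] = ()
    rereference: bool = True
    montage_path: str | None = None
    window_s: float = 2.0
    step_s: float = 1.0
    mpf_band: tuple[float, float] = sp.DEFAULT_BAND
    taper: str | None = None
    threshold_hz: float = ev.DEFAULT_THRESHOLD_HZ
    min_duration_s: float = ev.DEFAULT_MIN_DURATION_S
    sweep_thresholds: tuple[float, ...] = ev.DEFAULT_SWEEP_HZ
    pct_time_aggregate: str = "mean"
    count_aggregate: str = "sum"  # "all areas" event count: sum | mean

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("bandpass", "bandstop"):
            if d[key] is not None:
                d[key] = dataclasses.asdict(getattr(self, key))
        return d


@dataclass
class SubjectMetrics:
    """Per-area event metrics and band powers for one subject."""

    subject_id: str
    analyzed_duration_s: float
    events: list[ev.PSWEvent]
    per_area: pd.DataFrame  # area_id, n_events, events_per_min, pct_time
    band_powers: sp.BandPowerTable
    pct_time_subject: float
    missing_areas: frozenset[int] = frozenset()

    def to_frame(self) -> pd.DataFrame:
        df = self.per_area.copy()
        df.insert(0, "subject_id", self.subject_id)
        bp = self.band_powers
        for name in bp.bands:
            df[f"rel_{name}"] = [bp.rel_power(a, name) for a in df["area_id"]]
        return df


def run_subject_pipeline(rec: Recording, config: PipelineConfig | None = None) -> SubjectMetrics:
    """preprocess -> regionize -> spectral -> detect, in fixed order."""
    if config is None:
        config = PipelineConfig()
    try:
        clean = pp.preprocess_pipeline(
            rec,
            bandpass=config.bandpass,
            bandstop=config.bandstop,
            exclude=list(config.exclude),
            rereference=config.rereference,
        )
    except Exception as err:
        raise type(err)(f"[preprocess] {err}") from err
    montage = (
        rg.load_montage(config.montage_path) if config.montage_path else rg.default_montage()
    )
    region = rg.spatial_average(clean, montage)
    series = sp.mpf_timecourse(
        region,
        window_s=config.window_s,
        step_s=config.step_s,
        band=config.mpf_band,
        taper=config.taper,
    )
    bands = sp.relative_band_power(
        region,
        total_band=config.mpf_band,
        window_s=config.window_s,
        step_s=config.step_s,
        taper=config.taper,
    )
    duration = float(series[0].times_s[-1] + config.window_s)
    all_events: list[ev.PSWEvent] = []
    rows = []
    for s in series:
        evts = ev.detect_pswe(
            s, threshold_hz=config.threshold_hz, min_duration_s=config.min_duration_s
        )
        all_events.extend(evts)
        rows.append(
            {
                "area_id": s.area_id,
                "n_events": len(evts),
                "events_per_min": ev.events_per_minute(evts, duration),
                "pct_time": ev.percent_time_in_pswe(evts, duration),
            }
        )
    live_areas = [a for a in AREA_IDS if a not in region.missing]
    pct_subject = (
        ev.subject_percent_time(
            all_events, duration, area_ids=live_areas, aggregate=config.pct_time_aggregate
        )
        if live_areas
        else float("nan")
    )
    per_area = pd.DataFrame(rows)
    per_area.loc[per_area["area_id"].isin(region.missing), ["events_per_min", "pct_time"]] = np.nan
    return SubjectMetrics(
        subject_id=rec.subject_id,
        analyzed_duration_s=duration,
        events=all_events,
        per_area=per_area,
        band_powers=bands,
        pct_time_subject=pct_subject,
        missing_areas=region.missing,
    )


def run_cohort(
    recordings: Sequence[Recording], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every subject; return (long metrics table, event table)."""
    metrics = []
    event_frames = []
    for rec in recordings:
        m = run_subject_pipeline(rec, config)
        metrics.append(m.to_frame())
        event_frames.append(ev.events_to_frame(m.events))
    return (
        pd.concat(metrics, ignore_index=True),
        pd.concat(event_frames, ignore_index=True),
    )


@dataclass(frozen=True)
class TestResult:
    metric: str
    area_id: int | str
    test: str
    groups: tuple[str, ...] | str
    statistic: float
    p_value: float
    correction: str = "none"

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    rows = [
        {
            "metric": r.metric,
            "area_id": r.area_id,
            "test": r.test,
            "groups": r.groups if isinstance(r.groups, str) else "|".join(r.groups),
            "statistic": r.statistic,
            "p_value": r.p_value,
            "correction": r.correction,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided
    large-sample t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValidationError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_compare(
    metrics: pd.DataFrame,
    meta: pd.DataFrame,
    metric: str = "n_events",
    areas: Iterable[int] = AREA_IDS,
    alpha: float = 0.05,
) -> list[TestResult]:
    """Per-area Kruskal-Wallis omnibus; pairwise rank-sum follow-ups
    (unadjusted, LSD-analog) only when the omnibus rejects at ``alpha``.

    ``metrics`` is the long per-subject/per-area table; ``meta`` maps
    subject_id to group.  Subjects with a missing area are dropped
    pairwise for that area.
    """
    merged = metrics.merge(meta[["subject_id", "group"]], on="subject_id", how="inner")
    group_names = sorted(merged["group"].unique())
    if len(group_names) < 2:
        raise ValidationError("need at least 2 groups")
    results: list[TestResult] = []
    for area in areas:
        sub = merged[merged["area_id"] == area].dropna(subset=[metric])
        samples = [sub.loc[sub["group"] == g, metric].to_numpy() for g in group_names]
        if any(len(s) < 2 for s in samples):
            raise ValidationError(f"area {area}: every group needs >= 2 subjects")
        if np.ptp(np.concatenate(samples)) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*samples)
        results.append(
            TestResult(metric, area, "kruskal-wallis", "omnibus", float(stat), float(p))
        )
        if p < alpha:
            for ga, gb in combinations(group_names, 2):
                a = sub.loc[sub["group"] == ga, metric].to_numpy()
                b = sub.loc[sub["group"] == gb, metric].to_numpy()
                u, pu = sps.mannwhitneyu(a, b, alternative="two-sided")
                results.append(
                    TestResult(
                        metric, area, "rank-sum", (ga, gb), float(u), float(pu),
                        correction="unadjusted (LSD-analog)",
                    )
                )
    return results


def duration_correlation(
    metrics: pd.DataFrame,
    meta: pd.DataFrame,
    group: str | None = "PD",
    scope: int | str = "all",
    metric: str = "n_events",
    covariate: str = "covariate",
    count_aggregate: str = "sum",
) -> TestResult:
    """Spearman correlation between a covariate (disease-duration analog)
    and the per-subject event count, summed over areas for scope="all"."""
    meta_cols = meta[["subject_id", covariate] + (["group"] if "group" in meta else [])]
    merged = metrics.merge(meta_cols, on="subject_id", how="inner")
    if group is not None and "group" in merged:
        merged = merged[merged["group"] == group]
    merged = merged.dropna(subset=[metric, covariate])
    if scope == "all":
        agg = "sum" if count_aggregate == "sum" else "mean"
        per_subject = merged.groupby("subject_id").agg(
            value=(metric, agg), cov=(covariate, "first")
        )
    else:
        sub = merged[merged["area_id"] == scope]
        per_subject = sub.set_index("subject_id")[[metric, covariate]].rename(
            columns={metric: "value", covariate: "cov"}
        )
    rho, p = spearman_correlation(per_subject["cov"], per_subject["value"])
    return TestResult(
        metric=f"{metric}~{covariate}",
        area_id=scope,
        test="spearman",
        groups=group or "all",
        statistic=rho,
        p_value=p,
    )
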