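"""Synthetic resting-state EEG with planted slow-wave ground truth.

The background is synthesized in the frequency domain: a deterministic
1/f^exponent amplitude envelope with uniformly random phases per channel,
plus a narrow Gaussian alpha bump.  Frequency-domain shaping gives exact
control of the power-law slope, which filtered white noise does not.

Slow-wave episodes are sinusoidal bursts with a 0.5-s raised-cosine
onset/offset taper (broadband edges would leak high-frequency power into
the event).  Events are planted per channel, before any regional
averaging, and logged in the recording's annotation list.

The waveform model is an assumption: real paroxysmal slowing is only
characterized here by its median-frequency signature, not its morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PlacementError, ValidationError
from .recording import PlantedEvent, Recording, EEG
from .regions import AREA_NAMES, default_labels, default_montage

_BACKGROUND_RMS_UV = 10.0  # nominal scalp-EEG scale, microvolts


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic resting-state recording."""

    n_channels: int = 60
    duration_s: float = 240.0
    fs: float = 250.0
    spectral_exponent: float = 1.0
    alpha_freq: float = 10.0
    alpha_rel_amp: float = 1.5
    alpha_width_hz: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValidationError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.n_channels > 60:
            raise ValidationError(
                f"n_channels must be <= 60 (shipped montage size), got {self.n_channels}"
            )
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.alpha_rel_amp < 0:
            raise ValidationError(f"alpha_rel_amp must be >= 0, got {self.alpha_rel_amp}")
        if self.alpha_rel_amp > 0 and self.fs <= 2 * self.alpha_freq:
            raise ValidationError(
                f"fs={self.fs} must exceed twice alpha_freq={self.alpha_freq}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic multi-subject cohort.

    Per subject, a covariate (disease-duration analog) is drawn uniformly
    from ``covariate_range`` and the event count from a Poisson law with
    rate ``base_event_rate + rate_covariate_slope * covariate`` (clipped
    at zero) events per minute.
    """

    n_subjects_per_group: int = 31
    groups: tuple[str, ...] = ("PD",)
    base_event_rate: float = 0.5
    rate_covariate_slope: float = 0.0
    covariate_range: tuple[float, float] = (0.5, 10.0)
    event_duration_range_s: tuple[float, float] = (7.0, 15.0)
    event_freq_range_hz: tuple[float, float] = (2.0, 4.0)
    amplitude_ratio: float = 5.0
    seed: int = 0

    def validate(self, duration_s: float) -> None:
        if self.n_subjects_per_group < 1:
            raise ValidationError("n_subjects_per_group must be >= 1")
        if not self.groups:
            raise ValidationError("groups must be nonempty")
        if self.base_event_rate < 0:
            raise ValidationError("base_event_rate must be >= 0")
        for name in ("covariate_range", "event_duration_range_s", "event_freq_range_hz"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must be ordered (min <= max), got {lo} > {hi}")
        if self.event_duration_range_s[0] <= 0 or self.event_freq_range_hz[0] <= 0:
            raise ValidationError("event durations and frequencies must be positive")
        max_rate = max(
            self.base_event_rate + self.rate_covariate_slope * c
            for c in self.covariate_range
        )
        expected_busy = max_rate * (duration_s / 60.0) * self.event_duration_range_s[1]
        if expected_busy > 0.5 * len(AREA_NAMES) * duration_s:
            raise ValidationError(
                "expected event load exceeds half the per-region recording capacity; "
                "reduce rates or event durations"
            )


def generate_background(spec: SynthSpec) -> Recording:
    """1/f^exponent background noise with an alpha peak, per channel.

    Channels are labelled with the shipped 10-10 montage names,
    interleaved across areas so all 9 regions are covered whenever
    ``n_channels >= 9``.  Bit-identical output for identical spec+seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    n_bins = freqs.size

    # deterministic amplitude envelope, random phases
    amp = np.zeros(n_bins)
    pos = freqs > 0
    amp[pos] = freqs[pos] ** (-spec.spectral_exponent / 2.0)
    if n % 2 == 0:
        amp[-1] = 0.0  # drop the Nyquist bin to keep phases free
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_channels, n_bins))
    x = np.fft.irfft(amp * np.exp(1j * phases), n=n, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    x *= _BACKGROUND_RMS_UV / rms

    if spec.alpha_rel_amp > 0:
        bump = np.exp(-0.5 * ((freqs - spec.alpha_freq) / spec.alpha_width_hz) ** 2)
        bump[~pos] = 0.0
        if n % 2 == 0:
            bump[-1] = 0.0
        aphases = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_channels, n_bins))
        a = np.fft.irfft(bump * np.exp(1j * aphases), n=n, axis=-1)
        arms = np.sqrt(np.mean(a**2, axis=-1, keepdims=True))
        x += a * (spec.alpha_rel_amp * _BACKGROUND_RMS_UV / arms)

    labels = default_labels(spec.n_channels)
    return Recording(
        samples=x,
        fs=spec.fs,
        labels=labels,
        types=(EEG,) * spec.n_channels,
        subject_id=f"synth-{spec.seed}",
    )


def _burst(n: int, fs: float, freq: float, taper_s: float = 0.5) -> np.ndarray:
    """Unit-amplitude sinusoid with raised-cosine onset/offset ramps."""
    t = np.arange(n) / fs
    wave = np.sin(2.0 * np.pi * freq * t)
    ramp = min(int(round(taper_s * fs)), n // 2)
    env = np.ones(n)
    if ramp > 0:
        up = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = up
        env[-ramp:] = up[::-1]
    return wave * env


def plant_slow_event(rec: Recording, ev: PlantedEvent, taper_s: float = 0.5) -> Recording:
    """Add a tapered oscillation to the named channels; log the truth.

    The burst amplitude on each channel is scaled so its RMS (before
    tapering) equals ``amplitude_ratio`` times that channel's RMS.
    Samples outside the event window are untouched.
    """
    ev.validate(rec.duration_s, rec.labels)
    if ev.dominant_freq >= rec.fs / 2:
        raise ValidationError(
            f"dominant_freq {ev.dominant_freq} Hz is not below Nyquist {rec.fs / 2} Hz"
        )
    out = rec.copy()
    i0 = int(round(ev.start_s * rec.fs))
    i1 = int(round((ev.start_s + ev.duration_s) * rec.fs))
    i1 = min(i1, rec.n_times)
    if ev.amplitude_ratio != 0 and i1 > i0:
        burst = _burst(i1 - i0, rec.fs, ev.dominant_freq, taper_s)
        for label in ev.channel_set:
            ch = rec.index_of(label)
            ch_rms = np.sqrt(np.mean(rec.samples[ch] ** 2))
            amp = ev.amplitude_ratio * ch_rms * np.sqrt(2.0)
            out.samples[ch, i0:i1] += amp * burst
    out.annotations.append(replace(ev))
    return out


def _place_events(
    rng: np.random.Generator,
    n_events: int,
    duration_s: float,
    cspec: CohortSpec,
    max_attempts: int = 1000,
) -> list[tuple[int, float, float, float]]:
    """Draw (area, start, duration, freq) tuples, non-overlapping per area."""
    placed: dict[int, list[tuple[float, float]]] = {a: [] for a in AREA_NAMES}
    out = []
    for _ in range(n_events):
        for attempt in range(max_attempts):
            area = int(rng.integers(1, 10))
            dur = float(rng.uniform(*cspec.event_duration_range_s))
            if dur > duration_s:
                continue
            start = float(rng.uniform(0.0, duration_s - dur))
            if all(
                start + dur <= s0 or start >= s0 + d0 for s0, d0 in placed[area]
            ):
                placed[area].append((start, dur))
                freq = float(rng.uniform(*cspec.event_freq_range_hz))
                out.append((area, start, dur, freq))
                break
        else:
            raise PlacementError(
                f"could not place event {len(out) + 1}/{n_events} without overlap "
                f"after {max_attempts} attempts"
            )
    return out


def draw_cohort_events(
    cspec: CohortSpec, duration_s: float = 240.0
) -> tuple[pd.DataFrame, dict[str, list[tuple[int, float, float, float]]]]:
    """Sample the cohort's covariates and event placements (no waveforms).

    Returns the subject table (subject_id, group, covariate, event_rate,
    n_true_events) and the per-subject (area, start, duration, freq)
    placements.  This is the statistical layer of :func:`generate_cohort`
    and is useful on its own for calibration studies that do not need
    signal synthesis.
    """
    cspec.validate(duration_s)
    rng = np.random.default_rng(cspec.seed)
    rows = []
    placements: dict[str, list[tuple[int, float, float, float]]] = {}
    for group in cspec.groups:
        for i in range(cspec.n_subjects_per_group):
            sid = f"{group}-{i:03d}"
            covariate = float(rng.uniform(*cspec.covariate_range))
            rate = max(0.0, cspec.base_event_rate + cspec.rate_covariate_slope * covariate)
            n_events = int(rng.poisson(rate * duration_s / 60.0))
            placements[sid] = _place_events(rng, n_events, duration_s, cspec)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "covariate": covariate,
                    "event_rate": rate,
                    "n_true_events": n_events,
                }
            )
    return pd.DataFrame(rows), placements


def generate_cohort(
    cspec: CohortSpec, synth: SynthSpec | None = None
) -> tuple[list[Recording], pd.DataFrame]:
    """One recording per subject with Poisson-planted regional slow events.

    Every event covers all channels of one area (chosen uniformly), with
    start/duration/frequency drawn from the cohort spec's ranges and
    overlaps within an area rejected by resampling.  Reproducible from
    ``cspec.seed``: per-subject background seeds are spawned from it.
    """
    if synth is None:
        synth = SynthSpec()
    synth.validate()
    table, placements = draw_cohort_events(cspec, duration_s=synth.duration_s)
    montage = default_montage()
    available = {lbl.upper() for lbl in default_labels(synth.n_channels)}
    seed_seq = np.random.SeedSequence(cspec.seed)
    child_seeds = seed_seq.spawn(len(table))
    recordings = []
    for (_, row), child in zip(table.iterrows(), child_seeds):
        sub_spec = replace(synth, seed=int(child.generate_state(1)[0]))
        rec = generate_background(sub_spec)
        rec = replace(rec, subject_id=row["subject_id"])
        for area, start, dur, freq in placements[row["subject_id"]]:
            channels = tuple(l for l in montage.labels_in(area) if l in available)
            if not channels:
                continue
            rec = plant_slow_event(
                rec,
                PlantedEvent(
                    subject_id=row["subject_id"],
                    channel_set=channels,
                    start_s=start,
                    duration_s=dur,
                    dominant_freq=freq,
                    amplitude_ratio=cspec.amplitude_ratio,
                    area_id=area,
                ),
            )
        recordings.append(rec)
    return recordings, table


def truth_log_frame(recordings: list[Recording]) -> pd.DataFrame:
    """Flatten the annotation logs of a cohort into one table."""
    rows = []
    for rec in recordings:
        for ev in rec.annotations:
            rows.append(
                {
                    "subject_id": ev.subject_id,
                    "area_id": ev.area_id,
                    "start_s": ev.start_s,
                    "duration_s": ev.duration_s,
                    "dominant_freq": ev.dominant_freq,
                    "amplitude_ratio": ev.amplitude_ratio,
                    "channels": "|".join(ev.channel_set),
                }
            )
    cols = [
        "subject_id", "area_id", "start_s", "duration_s",
        "dominant_freq", "amplitude_ratio", "channels",
    ]
    return pd.DataFrame(rows, columns=cols)
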