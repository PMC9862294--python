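"""Sliding-window spectra, median power frequency, and band powers.

Conventions (recorded in output metadata, configurable):

* 2-s rectangular window, 1-s step, per-window mean removal; a Hann
  taper is available via ``taper="hann"``.
* Window power is normalized so that the one-sided spectrum sums to the
  mean square of the (detrended, tapered) segment (Parseval).
* The MPF integration band defaults to 1-45 Hz inclusive; the half-power
  crossing is located by linear interpolation between bin centers, and a
  cumulative sum landing exactly on half resolves to the lower frequency.
* Band powers use half-open bands [low, high) so shared edges (e.g. 5 Hz
  between delta and theta) are never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedMPFError, ValidationError
from .regions import RegionSeries

DEFAULT_BAND = (1.0, 45.0)
#: delta/theta/alpha/beta as used for the relative band-power tables
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 5.0),
    "theta": (5.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 20.0),
}


@dataclass
class Spectrum:
    """One-sided power spectrum of a single window."""

    freqs: np.ndarray
    power: np.ndarray
    window_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValidationError("freqs and power must be matching 1-D arrays")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValidationError("power must be nonnegative")


@dataclass
class MPFSeries:
    """Per-area time course of median power frequency over sliding windows.

    Undefined windows (zero band power) are NaN; a fully-missing area
    yields an all-NaN series.
    """

    area_id: int
    times_s: np.ndarray
    mpf_hz: np.ndarray
    window_s: float = 2.0
    step_s: float = 1.0
    band: tuple[float, float] = DEFAULT_BAND
    subject_id: str = "S000"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.mpf_hz = np.asarray(self.mpf_hz, dtype=np.float64)
        if self.times_s.shape != self.mpf_hz.shape:
            raise ValidationError("times_s and mpf_hz must have matching shapes")
        if self.times_s.size > 1:
            steps = np.diff(self.times_s)
            if not np.allclose(steps, self.step_s, rtol=0, atol=1e-9):
                raise ValidationError("times_s must be equally spaced by step_s")
        finite = self.mpf_hz[np.isfinite(self.mpf_hz)]
        lo, hi = self.band
        if finite.size and (finite.min() < lo - 1e-9 or finite.max() > hi + 1e-9):
            raise ValidationError("mpf values fall outside the integration band")


def _window_taper(n: int, taper: str | None) -> np.ndarray | None:
    if taper in (None, "none", "boxcar", "rect"):
        return None
    if taper == "hann":
        return np.hanning(n)
    raise ValidationError(f"unknown taper {taper!r}")


def _psd_matrix(segments: np.ndarray, fs: float, detrend: bool, taper: str | None):
    """One-sided power spectra of (n_windows, n_samples) segments.

    Normalized so each row sums to the mean square of its (processed)
    segment.
    """
    segs = np.asarray(segments, dtype=np.float64)
    n = segs.shape[-1]
    if detrend:
        segs = segs - segs.mean(axis=-1, keepdims=True)
    w = _window_taper(n, taper)
    if w is not None:
        segs = segs * w
        norm = n * np.sum(w**2)
    else:
        norm = float(n) * n
    spec = np.fft.rfft(segs, axis=-1)
    power = (spec.real**2 + spec.imag**2) / norm
    # double everything except DC and (for even n) the Nyquist bin
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def psd_window(
    segment: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    detrend: bool = True,
    taper: str | None = None,
    window_start_s: float = 0.0,
) -> Spectrum:
    """Power spectrum of one analysis window.

    The segment must be exactly ``window_s * fs`` samples long, giving a
    frequency resolution of ``1 / window_s`` (0.5 Hz at 2 s).
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 1:
        raise ValidationError("segment must be 1-D")
    expected = int(round(window_s * fs))
    if segment.size != expected:
        raise ValidationError(
            f"segment has {segment.size} samples; expected window_s*fs = {expected}"
        )
    freqs, power = _psd_matrix(segment[np.newaxis, :], fs, detrend, taper)
    return Spectrum(freqs=freqs, power=power[0], window_start_s=window_start_s)


def _mpf_rows(power: np.ndarray, freqs: np.ndarray, fmin: float, fmax: float) -> np.ndarray:
    """Vectorized half-power frequency for each row of ``power``.

    Rows with zero band power come back NaN.
    """
    sel = (freqs >= fmin - 1e-12) & (freqs <= fmax + 1e-12)
    if not np.any(sel):
        raise ValidationError(f"band [{fmin}, {fmax}] contains no frequency bins")
    f = freqs[sel]
    p = power[:, sel]
    cum = np.cumsum(p, axis=1)
    total = cum[:, -1]
    out = np.full(power.shape[0], np.nan)
    ok = total > 0
    if not np.any(ok):
        return out
    half = total[ok] / 2.0
    cs = cum[ok]
    # first bin index where the cumulative reaches half the band power
    k = np.array([np.searchsorted(row, h, side="left") for row, h in zip(cs, half)])
    prev_cum = np.where(k > 0, cs[np.arange(len(k)), np.maximum(k - 1, 0)], 0.0)
    prev_f = np.where(k > 0, f[np.maximum(k - 1, 0)], f[0])
    bin_p = p[ok][np.arange(len(k)), k]
    frac = (half - prev_cum) / bin_p
    mpf = np.where(k > 0, prev_f + (f[k] - prev_f) * frac, f[0])
    out[ok] = mpf
    return out


def median_power_frequency(
    spec: Spectrum, fmin: float = DEFAULT_BAND[0], fmax: float = DEFAULT_BAND[1]
) -> float:
    """Frequency at which cumulative band power first reaches half.

    Linear interpolation inside the crossing bin; exact half-crossings at
    a bin resolve to that (lower) bin frequency.  Raises
    :class:`UndefinedMPFError` if the band holds no power.
    """
    if fmin >= fmax:
        raise ValidationError(f"fmin must be < fmax, got ({fmin}, {fmax})")
    if fmin < spec.freqs[0] - 1e-9 or fmax > spec.freqs[-1] + 1e-9:
        raise ValidationError("requested band lies outside the spectrum range")
    mpf = _mpf_rows(spec.power[np.newaxis, :], spec.freqs, fmin, fmax)[0]
    if not np.isfinite(mpf):
        raise UndefinedMPFError(f"zero power in band [{fmin}, {fmax}] Hz")
    return float(mpf)


def _sliding_windows(x: np.ndarray, win: int, step: int) -> np.ndarray:
    """(n_windows, win) view over the last axis of a 1-D signal."""
    n_windows = (x.size - win) // step + 1
    idx = np.arange(win)[np.newaxis, :] + step * np.arange(n_windows)[:, np.newaxis]
    return x[idx]


def mpf_timecourse(
    region: RegionSeries,
    window_s: float = 2.0,
    step_s: float = 1.0,
    band: tuple[float, float] = DEFAULT_BAND,
    taper: str | None = None,
) -> list[MPFSeries]:
    """MPF per sliding window for each of the 9 areas.

    Windows start at 0, step_s, 2*step_s, ... while they fit entirely in
    the recording; a 240-s recording yields 239 windows at 2 s / 1 s.
    """
    win = int(round(window_s * region.fs))
    step = int(round(step_s * region.fs))
    if region.n_times < win:
        raise ValidationError(
            f"recording of {region.duration_s:.3f} s shorter than window {window_s} s"
        )
    out: list[MPFSeries] = []
    n_windows = (region.n_times - win) // step + 1
    times = np.arange(n_windows) * step_s
    for area_id in region.area_ids:
        sig = region.area_signal(area_id)
        if area_id in region.missing or not np.all(np.isfinite(sig)):
            mpf = np.full(n_windows, np.nan)
        else:
            segs = _sliding_windows(sig, win, step)
            freqs, power = _psd_matrix(segs, region.fs, detrend=True, taper=taper)
            mpf = _mpf_rows(power, freqs, band[0], band[1])
        out.append(
            MPFSeries(
                area_id=area_id,
                times_s=times,
                mpf_hz=mpf,
                window_s=window_s,
                step_s=step_s,
                band=band,
                subject_id=region.subject_id,
            )
        )
    return out


@dataclass
class BandPowerTable:
    """Relative power per area and band; values in [0, 1], NaN if missing."""

    values: dict[int, dict[str, float]]
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    total_band: tuple[float, float] = DEFAULT_BAND
    subject_id: str = "S000"

    def rel_power(self, area_id: int, band: str) -> float:
        return self.values[area_id][band]


def relative_band_power(
    region: RegionSeries,
    bands: dict[str, tuple[float, float]] | None = None,
    total_band: tuple[float, float] = DEFAULT_BAND,
    window_s: float = 2.0,
    step_s: float = 1.0,
    taper: str | None = None,
) -> BandPowerTable:
    """Welch-style mean of the sliding-window spectra, then band AUC ratios.

    Each band's relative power is its [low, high) bin mass divided by the
    [total_low, total_high) mass of the averaged spectrum.
    """
    if bands is None:
        bands = dict(DEFAULT_BANDS)
    win = int(round(window_s * region.fs))
    step = int(round(step_s * region.fs))
    if region.n_times < win:
        raise ValidationError("recording shorter than one analysis window")
    values: dict[int, dict[str, float]] = {}
    for area_id in region.area_ids:
        sig = region.area_signal(area_id)
        if area_id in region.missing or not np.all(np.isfinite(sig)):
            values[area_id] = {name: float("nan") for name in bands}
            continue
        segs = _sliding_windows(sig, win, step)
        freqs, power = _psd_matrix(segs, region.fs, detrend=True, taper=taper)
        mean_power = power.mean(axis=0)
        tot_sel = (freqs >= total_band[0] - 1e-12) & (freqs < total_band[1] - 1e-12)
        total = mean_power[tot_sel].sum()
        if total <= 0:
            raise UndefinedMPFError(
                f"zero total power in band {total_band} for area {area_id}"
            )
        row = {}
        for name, (lo, hi) in bands.items():
            sel = (freqs >= lo - 1e-12) & (freqs < hi - 1e-12)
            row[name] = float(mean_power[sel].sum() / total)
        values[area_id] = row
    return BandPowerTable(
        values=values, bands=dict(bands), total_band=total_band, subject_id=region.subject_id
    )
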