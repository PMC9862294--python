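"""FIR filtering, channel exclusion, average reference, EOG removal.

The source pipeline states only band edges (1-95 Hz pass, 45-55 Hz stop)
and "FIR"; design details are fixed here as: Hamming-windowed linear-phase
taps with length set by the standard transition-width rule (~3.3/N cycles
per sample), applied forward-backward (zero phase) so event timing is not
shifted.  Transition width defaults to 1 Hz at the 1 Hz edge and 2 Hz
elsewhere.  The band-stop is centred on 50 Hz mains; pass (55, 65) for
60 Hz regions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ChannelLookupError, ValidationError
from .recording import EEG, EOG, Recording

_HAMMING_TRANSITION_CYCLES = 3.3


@dataclass(frozen=True)
class FilterSpec:
    """Band edges and transition widths of one FIR stage."""

    kind: str  # "bandpass" | "bandstop"
    low_hz: float
    high_hz: float
    transition_hz: tuple[float, float] = (2.0, 2.0)

    def validate(self, fs: float) -> None:
        if self.kind not in ("bandpass", "bandstop"):
            raise ValidationError(f"kind must be bandpass or bandstop, got {self.kind!r}")
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        if self.high_hz >= fs / 2:
            raise ValidationError(
                f"high_hz {self.high_hz} Hz must be below Nyquist {fs / 2} Hz"
            )
        if min(self.transition_hz) <= 0:
            raise ValidationError("transition widths must be > 0")


BANDPASS_DEFAULT = FilterSpec("bandpass", 1.0, 95.0, transition_hz=(1.0, 2.0))
BANDSTOP_DEFAULT = FilterSpec("bandstop", 45.0, 55.0, transition_hz=(2.0, 2.0))


def design_taps(spec: FilterSpec, fs: float) -> np.ndarray:
    """Hamming-window FIR taps for a FilterSpec.

    The -6 dB cutoffs sit half a transition width beyond the band edges
    (outward for bandpass, inward for bandstop) so the stated edges land
    in the flat part of the response, and the stopband begins one
    transition width past them.
    """
    spec.validate(fs)
    t_lo, t_hi = spec.transition_hz
    numtaps = int(np.ceil(_HAMMING_TRANSITION_CYCLES * fs / min(t_lo, t_hi)))
    numtaps += 1 - numtaps % 2  # odd length -> type I linear phase
    if spec.kind == "bandpass":
        cutoffs = [max(spec.low_hz - t_lo / 2, 1e-6), spec.high_hz + t_hi / 2]
        if cutoffs[1] >= fs / 2:
            cutoffs[1] = (spec.high_hz + fs / 2) / 2
        return signal.firwin(numtaps, cutoffs, pass_zero=False, window="hamming", fs=fs)
    cutoffs = [spec.low_hz + t_lo / 2, spec.high_hz - t_hi / 2]
    if cutoffs[0] >= cutoffs[1]:
        raise ValidationError("transition widths too wide for the stop band")
    return signal.firwin(numtaps, cutoffs, pass_zero=True, window="hamming", fs=fs)


def frequency_response(taps: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Single-pass magnitude response of the taps at the given frequencies."""
    _, h = signal.freqz(taps, worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h)


def fir_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase (forward-backward) application of the designed FIR."""
    taps = design_taps(spec, rec.fs)
    if rec.n_times < 3 * taps.size:
        raise ValidationError(
            f"recording of {rec.n_times} samples is shorter than 3x filter "
            f"length ({3 * taps.size} samples)"
        )
    filtered = signal.filtfilt(taps, [1.0], rec.samples, axis=-1)
    return replace(rec, samples=filtered, annotations=list(rec.annotations))


def exclude_channels(rec: Recording, bad_labels: list[str]) -> Recording:
    """Drop the named channels, preserving the order of the rest."""
    bad = {l.strip().upper() for l in bad_labels}
    known = {l.strip().upper() for l in rec.labels}
    unknown = sorted(bad - known)
    if unknown:
        raise ChannelLookupError(f"cannot exclude unknown channels: {unknown}")
    keep = [i for i, l in enumerate(rec.labels) if l.strip().upper() not in bad]
    return rec.pick(keep)


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean of all EEG channels from each EEG channel.

    EOG channels are untouched.  Idempotent.
    """
    eeg = rec.eeg_mask
    if eeg.sum() < 2:
        raise ValidationError("average reference needs at least 2 EEG channels")
    out = rec.copy()
    out.samples[eeg] -= out.samples[eeg].mean(axis=0, keepdims=True)
    return out


def drop_eog(rec: Recording) -> Recording:
    """Remove all EOG-typed channels (no-op if none are present)."""
    keep = [i for i, t in enumerate(rec.types) if t == EEG]
    if len(keep) == rec.n_channels:
        return rec.copy()
    return rec.pick(keep)


def preprocess_pipeline(
    rec: Recording,
    bandpass: FilterSpec | None = BANDPASS_DEFAULT,
    bandstop: FilterSpec | None = BANDSTOP_DEFAULT,
    exclude: list[str] | None = None,
    rereference: bool = True,
) -> Recording:
    """Fixed-order driver: bandpass -> bandstop -> exclude -> rereference -> drop EOG.

    ``rereference=False`` skips the average-reference stage.  Note that
    average referencing mixes a spatially confined slow event into every
    other channel (sign-inverted), so localized synthetic events appear
    in all areas downstream; disable it when validating against planted
    per-region ground truth.
    """
    out = rec
    if bandpass is not None:
        out = fir_filter(out, bandpass)
    if bandstop is not None:
        out = fir_filter(out, bandstop)
    if exclude:
        out = exclude_channels(out, exclude)
    if rereference:
        out = rereference_average(out)
    return drop_eog(out)


def assign_types_by_pattern(rec: Recording, eog_prefix: str = "EOG") -> Recording:
    """Label-pattern channel typing: labels starting with the prefix -> EOG."""
    types = tuple(
        EOG if l.strip().upper().startswith(eog_prefix.upper()) else EEG
        for l in rec.labels
    )
    return replace(rec, types=types, annotations=list(rec.annotations))
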