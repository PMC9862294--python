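"""Core in-memory representation of a multi-channel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ChannelLookupError, ValidationError

EEG = "EEG"
EOG = "EOG"


@dataclass
class PlantedEvent:
    """Ground-truth record of one synthetic slow-wave episode.

    ``amplitude_ratio`` is the ratio of the oscillation RMS to the
    per-channel background RMS at planting time.
    """

    subject_id: str
    channel_set: tuple[str, ...]
    start_s: float
    duration_s: float
    dominant_freq: float
    amplitude_ratio: float
    area_id: int | None = None

    def validate(self, duration_s: float, labels: Sequence[str]) -> None:
        from .errors import RangeError

        if self.start_s < 0:
            raise RangeError(f"event start_s must be >= 0, got {self.start_s}")
        if self.duration_s <= 0:
            raise ValidationError(f"event duration_s must be > 0, got {self.duration_s}")
        if self.start_s + self.duration_s > duration_s + 1e-9:
            raise RangeError(
                f"event [{self.start_s}, {self.start_s + self.duration_s}] s exceeds "
                f"recording duration {duration_s} s"
            )
        if self.dominant_freq <= 0:
            raise ValidationError(f"dominant_freq must be > 0, got {self.dominant_freq}")
        known = set(labels)
        unknown = [c for c in self.channel_set if c not in known]
        if unknown:
            raise ChannelLookupError(f"unknown channels in event: {unknown}")


@dataclass
class Recording:
    """Channels-by-time sample matrix with label/type metadata.

    ``samples`` is (n_channels, n_times) in microvolts.  ``annotations``
    carries the planted-event truth log for synthetic recordings.
    """

    samples: np.ndarray
    fs: float
    labels: tuple[str, ...]
    types: tuple[str, ...]
    subject_id: str = "S000"
    annotations: list[PlantedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = tuple(self.labels)
        self.types = tuple(self.types)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (channels x time) array")
        if len(self.labels) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channel rows"
            )
        if len(self.types) != len(self.labels):
            raise ValidationError("types must align with labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate channel labels")
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    @property
    def eeg_mask(self) -> np.ndarray:
        return np.asarray([t == EEG for t in self.types])

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ChannelLookupError(f"no channel named {label!r}") from None

    def copy(self) -> "Recording":
        return replace(
            self,
            samples=self.samples.copy(),
            annotations=list(self.annotations),
        )

    def pick(self, indices: Sequence[int]) -> "Recording":
        idx = list(indices)
        return replace(
            self,
            samples=self.samples[idx].copy(),
            labels=tuple(self.labels[i] for i in idx),
            types=tuple(self.types[i] for i in idx),
            annotations=list(self.annotations),
        )
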