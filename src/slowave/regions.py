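"""Map 10-10 electrode labels onto 9 scalp areas and average within areas.

Area numbering: 1 right frontal, 2 left frontal, 3 central frontal,
4 right tempo-parietal, 5 left tempo-parietal, 6 central tempo-parietal,
7 right occipital, 8 left occipital, 9 central occipital.

The label-to-area rule is purely lexical: the letter prefix selects the
lobe group (Fp/AF/F frontal; FC/FT/C/T/CP/TP/P tempo-parietal; PO/O
occipital) and the suffix selects laterality (odd digit left, even digit
right, trailing "z" midline).  The shipped default montage is this rule
applied to a fixed 60-label 10-10 subset; users can override it with any
two-column (label, area_id) delimited file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ChannelLookupError, ValidationError
from .recording import EEG, Recording

AREA_NAMES: dict[int, str] = {
    1: "right frontal",
    2: "left frontal",
    3: "central frontal",
    4: "right tempo-parietal",
    5: "left tempo-parietal",
    6: "central tempo-parietal",
    7: "right occipital",
    8: "left occipital",
    9: "central occipital",
}

_FRONTAL = {"FP", "AF", "F"}
_TEMPOPARIETAL = {"FC", "FT", "C", "T", "CP", "TP", "P"}
_OCCIPITAL = {"PO", "O"}

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|Z|\d+)$")


def area_for_label(label: str) -> int:
    """Assign a 10-10 label to an area id (1-9) by the lexical rule."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ChannelLookupError(f"label {label!r} is not a recognizable 10-10 name")
    prefix, suffix = m.group(1).upper(), m.group(2)
    if prefix in _FRONTAL:
        base = 0
    elif prefix in _TEMPOPARIETAL:
        base = 3
    elif prefix in _OCCIPITAL:
        base = 6
    else:
        raise ChannelLookupError(f"label {label!r}: unknown prefix {prefix!r}")
    if suffix.upper() == "Z":
        side = 3  # midline
    elif int(suffix) % 2 == 1:
        side = 2  # odd -> left
    else:
        side = 1  # even -> right
    return base + side


@dataclass(frozen=True)
class MontageMap:
    """Immutable mapping from (upper-cased) channel labels to area ids."""

    assignment: dict[str, int]
    area_names: dict[int, str] = field(default_factory=lambda: dict(AREA_NAMES))

    def __post_init__(self) -> None:
        for label, area in self.assignment.items():
            if area not in AREA_NAMES:
                raise ValidationError(f"label {label!r} mapped to invalid area {area}")

    def area_of(self, label: str) -> int:
        try:
            return self.assignment[label.strip().upper()]
        except KeyError:
            raise ChannelLookupError(f"channel {label!r} not in montage") from None

    def labels_in(self, area_id: int) -> list[str]:
        return sorted(l for l, a in self.assignment.items() if a == area_id)

    def __contains__(self, label: str) -> bool:
        return label.strip().upper() in self.assignment


def load_montage(path: str | Path) -> MontageMap:
    """Read a (label, area_id) delimited file with a header row."""
    assignment: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        delim = "\t" if "\t" in header else ","
        for line in fh:
            line = line.strip()
            if not line:
                continue
            label, area = line.split(delim)[:2]
            assignment[label.strip().upper()] = int(area)
    if not assignment:
        raise ValidationError(f"montage file {path} contains no assignments")
    return MontageMap(assignment)


def default_montage() -> MontageMap:
    """The shipped 60-channel 10-10 montage covering all 9 areas."""
    ref = resources.files("slowave.data").joinpath("montage_1010_60.tsv")
    with resources.as_file(ref) as path:
        montage = load_montage(path)
    return montage


def default_labels(n_channels: int = 60) -> tuple[str, ...]:
    """The first ``n_channels`` default labels, interleaved across areas.

    Interleaving means any prefix of length >= 9 already touches all 9
    areas, so reduced-size synthetic recordings still exercise every
    region.
    """
    if not 1 <= n_channels <= 60:
        raise ValidationError(f"n_channels must be in [1, 60], got {n_channels}")
    montage = default_montage()
    by_area = {a: montage.labels_in(a) for a in AREA_NAMES}
    ordered: list[str] = []
    rank = 0
    while len(ordered) < 60:
        for area in sorted(by_area):
            if rank < len(by_area[area]):
                ordered.append(by_area[area][rank])
        rank += 1
    return tuple(ordered[:n_channels])


@dataclass
class RegionSeries:
    """9 regional average signals; missing areas hold NaN rows."""

    samples: np.ndarray  # (9, n_times)
    fs: float
    subject_id: str
    area_ids: tuple[int, ...] = tuple(range(1, 10))
    missing: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape[0] != 9 or self.area_ids != tuple(range(1, 10)):
            raise ValidationError("RegionSeries must have exactly 9 rows in area order 1..9")

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def area_signal(self, area_id: int) -> np.ndarray:
        return self.samples[area_id - 1]


def spatial_average(
    rec: Recording,
    montage: MontageMap | None = None,
    ignore: Iterable[str] = (),
) -> RegionSeries:
    """Unweighted mean of raw member-channel signals per area.

    Signals are not normalized before averaging.  EEG channels absent
    from the montage raise unless listed in ``ignore``; areas left with
    no member channels are flagged missing (NaN), never zeroed.
    """
    if montage is None:
        montage = default_montage()
    ignorable = {l.strip().upper() for l in ignore}
    members: dict[int, list[int]] = {a: [] for a in AREA_NAMES}
    for i, (label, typ) in enumerate(zip(rec.labels, rec.types)):
        if typ != EEG:
            continue
        key = label.strip().upper()
        if key in ignorable:
            continue
        if key not in montage:
            raise ChannelLookupError(
                f"EEG channel {label!r} is not assigned in the montage "
                "(pass ignore=[...] to skip it)"
            )
        members[montage.area_of(label)].append(i)

    out = np.full((9, rec.n_times), np.nan)
    missing = set()
    for area in AREA_NAMES:
        idx = members[area]
        if idx:
            out[area - 1] = rec.samples[idx].mean(axis=0)
        else:
            missing.add(area)
    return RegionSeries(
        samples=out, fs=rec.fs, subject_id=rec.subject_id, missing=frozenset(missing)
    )
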