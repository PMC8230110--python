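"""Core domain containers for the pulsatility pipeline.

The pipeline input is a :class:`RawNIRSRecording`: a multi-channel raw
intensity matrix from a dual-wavelength (735/850 nm) continuous-wave NIRS
device sampled at 20 Hz, together with its optode :class:`Montage`, a triaxial
accelerometer trace and segment annotations for the walking paradigm
(standing rest before walking, walk, standing rest after walking).
Downstream stages produce :class:`HeartbeatEpoch`, :class:`ChannelPulsatility`
and :class:`GlobalPulseAmplitude` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Annotation",
    "Montage",
    "RawNIRSRecording",
    "HeartbeatEpoch",
    "ChannelPulsatility",
    "GlobalPulseAmplitude",
    "ContrastResult",
    "SEGMENT_LABELS",
    "WAVELENGTHS",
    "PulsewalkError",
    "FormatError",
    "SchemaError",
    "DataError",
    "ParameterError",
]

SEGMENT_LABELS = ("BW", "WALK", "AW")
WAVELENGTHS = (735, 850)

MONTAGE_COLUMNS = [
    "channel_id",
    "source_id",
    "detector_id",
    "wavelength",
    "separation",
    "label",
    "x",
    "y",
    "z",
]


class PulsewalkError(Exception):
    """Base class for pipeline errors."""


class FormatError(PulsewalkError):
    """A file is missing or not in the expected on-disk format."""


class SchemaError(PulsewalkError):
    """File contents disagree with their declared schema (e.g. montage)."""


class DataError(PulsewalkError):
    """Values violate a domain invariant (duplicates, non-monotone time...)."""


class ParameterError(PulsewalkError):
    """A caller-supplied parameter is outside its valid range."""


@dataclass(frozen=True)
class Annotation:
    """Half-open time interval [start_s, end_s) labelled BW, WALK or AW."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise DataError(f"unknown annotation label {self.label!r}")
        if not self.end_s > self.start_s:
            raise DataError(
                f"annotation {self.label}: end {self.end_s} <= start {self.start_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


class Montage:
    """Optode montage: one row per channel = (source, detector, wavelength).

    Channels come in wavelength pairs: every 850 nm channel shares its
    source/detector with a 735 nm channel.  Separation is the scalp
    source-detector distance in cm; ``label`` is the 10-20 position of the
    channel midpoint and ``x, y, z`` its coordinates in cm.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy().reset_index(drop=True)
        missing = [c for c in MONTAGE_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"montage missing columns: {missing}")
        table["wavelength"] = table["wavelength"].astype(int)
        self.table = table[MONTAGE_COLUMNS]
        self._validate()

    def _validate(self) -> None:
        t = self.table
        if t["channel_id"].duplicated().any():
            raise SchemaError("duplicate channel_id in montage")
        bad_wl = set(t["wavelength"]) - set(WAVELENGTHS)
        if bad_wl:
            raise SchemaError(f"unsupported wavelengths {sorted(bad_wl)}")
        if (t["separation"] <= 0).any():
            raise SchemaError("non-positive source-detector separation")
        if t.duplicated(subset=["source_id", "detector_id", "wavelength"]).any():
            raise SchemaError("duplicate (source, detector, wavelength) in montage")
        # every 850 channel must have a 735 partner on the same optode pair
        key = t.set_index(["source_id", "detector_id", "wavelength"])
        for _, row in t[t["wavelength"] == 850].iterrows():
            if (row["source_id"], row["detector_id"], 735) not in key.index:
                raise SchemaError(
                    f"850 nm channel {row['channel_id']} lacks a 735 nm partner"
                )

    @property
    def channel_ids(self) -> list[str]:
        return list(self.table["channel_id"])

    @property
    def n_channels(self) -> int:
        return len(self.table)

    def row(self, channel_id: str) -> pd.Series:
        hit = self.table[self.table["channel_id"] == channel_id]
        if hit.empty:
            raise KeyError(channel_id)
        return hit.iloc[0]

    def wavelength_pairs(self) -> list[tuple[str, str]]:
        """(735 nm channel_id, 850 nm channel_id) per source-detector pair."""
        t = self.table
        pairs = []
        by_key = {
            (r["source_id"], r["detector_id"], r["wavelength"]): r["channel_id"]
            for _, r in t.iterrows()
        }
        for _, r in t[t["wavelength"] == 850].iterrows():
            pairs.append(
                (by_key[(r["source_id"], r["detector_id"], 735)], r["channel_id"])
            )
        return pairs

    def subset(self, channel_ids: Sequence[str]) -> "Montage":
        keep = self.table[self.table["channel_id"].isin(list(channel_ids))]
        return Montage(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Montage):
            return NotImplemented
        return self.table.reset_index(drop=True).equals(
            other.table.reset_index(drop=True)
        )

    def __repr__(self) -> str:
        return f"Montage({self.n_channels} channels)"


@dataclass
class RawNIRSRecording:
    """One walking-paradigm NIRS acquisition block for one participant.

    ``intensity`` is channels x samples in arbitrary detector units, channel
    order matching ``montage``; ``accel`` is 3 x samples in g.
    """

    sampling_rate: float
    intensity: np.ndarray
    montage: Montage
    accel: np.ndarray
    annotations: list[Annotation]
    participant_id: str = "P00"
    timepoint: str = "T0"
    block: int = 1
    meta: dict = field(default_factory=dict)

    CARDIAC_BAND_HIGH_HZ = 5.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.intensity.ndim != 2:
            raise DataError("intensity must be 2-D (channels x samples)")
        if self.intensity.shape[0] != self.montage.n_channels:
            raise SchemaError(
                f"intensity has {self.intensity.shape[0]} channels, montage "
                f"declares {self.montage.n_channels}"
            )
        if not np.isfinite(self.intensity).all():
            raise DataError("non-finite intensity samples")
        if self.sampling_rate <= 2 * self.CARDIAC_BAND_HIGH_HZ:
            raise ParameterError(
                f"sampling rate {self.sampling_rate} Hz cannot resolve the "
                f"cardiac band (needs > {2 * self.CARDIAC_BAND_HIGH_HZ} Hz)"
            )
        if self.accel.shape != (3, self.intensity.shape[1]):
            raise SchemaError("accelerometer must be 3 x n_samples, aligned")
        if self.timepoint not in ("T0", "T12"):
            raise DataError(f"timepoint must be T0 or T12, got {self.timepoint!r}")
        last_end = -np.inf
        for ann in self.annotations:
            if ann.start_s < last_end:
                raise DataError("annotations overlap or are out of order")
            last_end = ann.end_s
        if self.annotations and last_end > self.duration_s + 1e-9:
            raise DataError("annotation extends past end of recording")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        idx = self.montage.channel_ids.index(channel_id)
        return self.intensity[idx]

    def with_channels(self, channel_ids: Sequence[str]) -> "RawNIRSRecording":
        ids = [c for c in self.montage.channel_ids if c in set(channel_ids)]
        idx = [self.montage.channel_ids.index(c) for c in ids]
        return replace(
            self,
            intensity=self.intensity[idx],
            montage=self.montage.subset(ids),
        )


@dataclass
class HeartbeatEpoch:
    """One detected cardiac cycle on one channel.

    ``amplitude`` is the systolic peak minus the mean of the two flanking
    diastolic nadirs, in normalized-intensity units.
    """

    peak_idx: int
    nadir_left_idx: int
    nadir_right_idx: int
    amplitude: float
    duration_s: float
    valid: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if not (self.nadir_left_idx < self.peak_idx < self.nadir_right_idx):
            raise DataError("epoch indices must satisfy nadir_left < peak < nadir_right")


@dataclass
class ChannelPulsatility:
    """Per-channel quality metrics and robust pulse amplitude."""

    channel_id: str
    sci: float
    separation: float
    n_epochs: int
    amplitude: float
    heart_rate: float
    retained: bool
    reason: str = ""


@dataclass
class GlobalPulseAmplitude:
    """Mean pulse amplitude over retained channels for one rest segment."""

    participant_id: str
    timepoint: str
    condition: str
    block: int
    value: float
    n_channels: int
    heart_rate: float = float("nan")


@dataclass
class ContrastResult:
    """Paired-contrast output (global or one channel)."""

    scope: str
    statistic: float
    df: int
    p_raw: float
    effect: float
    n: int
    q_fdr: float = float("nan")
    channel_id: str = ""
    significant: bool | None = None
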