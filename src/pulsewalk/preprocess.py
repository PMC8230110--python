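"""Channel hygiene, segmentation, normalization, cardiac band-pass, masking.

The analysis units are the two standing-rest segments flanking the walk
(before-walking BW and after-walking AW); each retained channel is
normalized to its segment mean over artifact-free samples, band-passed to
the cardiac band (0.5-5 Hz, zero-phase Butterworth), and motion-masked
using the signal itself and the accelerometer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import (
    Annotation,
    DataError,
    ParameterError,
    RawNIRSRecording,
)

__all__ = [
    "Segmentation",
    "CleanSegment",
    "drop_saturated_channels",
    "segment_from_accelerometer",
    "normalize_to_mean",
    "bandpass_cardiac",
    "mask_motion_artifacts",
    "clean_segment",
]

CARDIAC_BAND_HZ = (0.5, 5.0)


@dataclass
class Segmentation:
    """BW / WALK / AW intervals, from annotations or the accelerometer."""

    intervals: list[Annotation]
    source: str  # "annotations" | "accelerometer"

    def __post_init__(self) -> None:
        order = [a.label for a in self.intervals]
        want = [l for l in ("BW", "WALK", "AW") if l in order]
        if order != want:
            raise DataError(f"segments out of order: {order}")

    def get(self, label: str) -> Annotation:
        for a in self.intervals:
            if a.label == label:
                return a
        raise KeyError(label)


@dataclass
class CleanSegment:
    """Normalized, band-passed channels for one rest segment."""

    label: str
    sampling_rate: float
    start_idx: int
    channel_ids: list[str]
    series: dict[str, np.ndarray]  # channel_id -> band-passed normalized trace
    mask: dict[str, np.ndarray]  # channel_id -> True where artifact
    channels_dropped: dict[str, str] = field(default_factory=dict)

    @property
    def masked_fraction(self) -> dict[str, float]:
        return {c: float(m.mean()) for c, m in self.mask.items()}


def drop_saturated_channels(
    rec: RawNIRSRecording,
    ceiling: float | None = None,
    max_frac: float = 0.01,
) -> tuple[RawNIRSRecording, dict[str, str]]:
    """Remove channels clipped at the detector ceiling or with zero variance.

    A channel is dropped when more than ``max_frac`` of its samples sit at or
    above ``ceiling`` (default: the detector ceiling recorded in the file
    metadata, else the per-recording intensity maximum), or when it carries
    no signal at all (zero variance).  The wavelength partner of a dropped
    channel is dropped with it — an optode pair with one unusable
    wavelength cannot be quality-checked.
    """
    if ceiling is None:
        ceiling = float(rec.meta.get("saturation_ceiling", rec.intensity.max()))
    if ceiling <= 0:
        raise ParameterError("saturation ceiling must be > 0")
    dropped: dict[str, str] = {}
    for i, cid in enumerate(rec.montage.channel_ids):
        x = rec.intensity[i]
        frac = float(np.mean(x >= ceiling))
        if frac > max_frac:
            dropped[cid] = f"saturated ({frac:.1%} of samples at ceiling)"
        elif float(np.var(x)) == 0.0:
            dropped[cid] = "zero variance"
    # propagate to wavelength partners
    tbl = rec.montage.table.set_index("channel_id")
    by_pair = {
        (r["source_id"], r["detector_id"], r["wavelength"]): cid
        for cid, r in tbl.iterrows()
    }
    for cid in list(dropped):
        r = tbl.loc[cid]
        other_wl = 735 if r["wavelength"] == 850 else 850
        partner = by_pair.get((r["source_id"], r["detector_id"], other_wl))
        if partner is not None and partner not in dropped:
            dropped[partner] = f"wavelength partner {cid} dropped"
    keep = [c for c in rec.montage.channel_ids if c not in dropped]
    if not keep:
        raise DataError("all channels dropped as saturated/flat")
    return rec.with_channels(keep), dropped


def segment_from_accelerometer(
    accel: np.ndarray,
    fs: float,
    walk_sd_factor: float = 3.0,
    min_bout_s: float = 5.0,
    annotations: list[Annotation] | None = None,
) -> Segmentation:
    """Locate the walking bout from accelerometer magnitude variability.

    WALK is where the 1 s moving standard deviation of the acceleration
    magnitude exceeds ``walk_sd_factor`` times the standing-baseline level
    (20th percentile of the moving sd) for at least ``min_bout_s``; BW and
    AW are the flanking rests.  When file annotations are supplied they are
    returned verbatim.
    """
    if annotations:
        return Segmentation(intervals=list(annotations), source="annotations")
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[0] != 3:
        raise ParameterError("accel must be 3 x n_samples")
    n = accel.shape[1]
    mag = np.linalg.norm(accel, axis=0)
    win = max(int(round(fs)), 2)
    pad = win // 2
    padded = np.pad(mag, pad, mode="edge")
    kernel = np.ones(win) / win
    mean = np.convolve(padded, kernel, mode="same")[pad : pad + n]
    meansq = np.convolve(padded**2, kernel, mode="same")[pad : pad + n]
    mov_sd = np.sqrt(np.maximum(meansq - mean**2, 0.0))

    baseline = np.percentile(mov_sd, 20)
    if baseline <= 0:
        baseline = np.finfo(float).tiny
    active = mov_sd > walk_sd_factor * baseline

    # longest contiguous active run
    best = None
    i = 0
    while i < n:
        if active[i]:
            j = i
            while j < n and active[j]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j
        else:
            i += 1
    if best is None or (best[1] - best[0]) / fs < min_bout_s:
        raise DataError("no walking bout found in accelerometer trace")
    w0, w1 = best[0] / fs, best[1] / fs
    duration = n / fs
    intervals = []
    if w0 > 0:
        intervals.append(Annotation("BW", 0.0, w0))
    intervals.append(Annotation("WALK", w0, w1))
    if w1 < duration:
        intervals.append(Annotation("AW", w1, duration))
    return Segmentation(intervals=intervals, source="accelerometer")


def normalize_to_mean(series: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Divide by the mean over unmasked samples; gain-invariant."""
    series = np.asarray(series, dtype=float)
    keep = ~mask if mask is not None else np.ones(len(series), dtype=bool)
    if not keep.any():
        raise DataError("all samples masked; cannot normalize")
    mu = float(series[keep].mean())
    if mu == 0.0 or not np.isfinite(mu):
        raise DataError("zero or non-finite mean; cannot normalize")
    return series / mu


def bandpass_cardiac(
    series: np.ndarray,
    fs: float,
    low: float = CARDIAC_BAND_HZ[0],
    high: float = CARDIAC_BAND_HZ[1],
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (applied forward-backward).

    Preserves cardiac peak timing (no group delay) while removing slow
    drifts and high-frequency noise.
    """
    if fs <= 2 * high:
        raise ParameterError(
            f"sampling rate {fs} Hz too low for {high} Hz upper cutoff"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(series, dtype=float))


def mask_motion_artifacts(
    series: np.ndarray,
    accel: np.ndarray | None,
    fs: float,
    amp_factor: float = 8.0,
    accel_factor: float = 8.0,
    pad_s: float = 0.5,
) -> np.ndarray:
    """Flag motion-contaminated samples from the signal and accelerometer.

    A sample is flagged where the 0.5 s moving amplitude range of the
    (normalized) signal exceeds ``amp_factor`` times a robust sd (MAD x
    1.4826) of the series, or where accelerometer jerk exceeds
    ``accel_factor`` times its own robust sd.  Flags are padded by
    ``pad_s`` on both sides.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    mask = np.zeros(n, dtype=bool)
    win = max(int(round(0.5 * fs)), 2)

    robust_sd = 1.4826 * np.median(np.abs(series - np.median(series)))
    if robust_sd > 0:
        from numpy.lib.stride_tricks import sliding_window_view

        rng_view = sliding_window_view(np.pad(series, win // 2, mode="edge"), win)
        local_range = rng_view.max(axis=1) - rng_view.min(axis=1)
        local_range = local_range[:n]
        mask |= local_range > amp_factor * robust_sd

    if accel is not None:
        accel = np.asarray(accel, dtype=float)
        mag = np.linalg.norm(accel, axis=0) if accel.ndim == 2 else accel
        jerk = np.abs(np.diff(mag, prepend=mag[0])) * fs
        jerk_sd = 1.4826 * np.median(np.abs(jerk - np.median(jerk)))
        if jerk_sd > 0:
            mask |= jerk > accel_factor * jerk_sd

    if mask.any():
        pad = int(round(pad_s * fs))
        idx = np.flatnonzero(mask)
        out = np.zeros(n, dtype=bool)
        for i in idx:
            out[max(0, i - pad) : min(n, i + pad + 1)] = True
        mask = out
    return mask


def clean_segment(
    rec: RawNIRSRecording,
    interval: Annotation,
    amp_factor: float = 8.0,
    accel_factor: float = 8.0,
    pad_s: float = 0.5,
) -> CleanSegment:
    """Normalize + band-pass + motion-mask all channels over one rest segment.

    Normalization is computed per segment over unmasked samples (the rest
    segments are the analysis units).  The returned traces have near-zero
    mean (DC is removed by the band-pass).
    """
    fs = rec.sampling_rate
    i0, i1 = int(round(interval.start_s * fs)), int(round(interval.end_s * fs))
    i1 = min(i1, rec.n_samples)
    if i1 - i0 < int(5 * fs):
        raise DataError(
            f"{interval.label} segment too short ({(i1 - i0) / fs:.1f} s) for analysis"
        )
    accel_seg = rec.accel[:, i0:i1]

    series: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    dropped: dict[str, str] = {}
    for idx, cid in enumerate(rec.montage.channel_ids):
        raw = rec.intensity[idx, i0:i1]
        premask = mask_motion_artifacts(
            raw / np.mean(raw) if np.mean(raw) != 0 else raw,
            accel_seg,
            fs,
            amp_factor=amp_factor,
            accel_factor=accel_factor,
            pad_s=pad_s,
        )
        if premask.all():
            dropped[cid] = "fully masked by motion artifacts"
            continue
        try:
            norm = normalize_to_mean(raw, premask)
        except DataError as e:
            dropped[cid] = str(e)
            continue
        filt = bandpass_cardiac(norm, fs)
        filt -= filt.mean()  # edge transients leave a tiny DC residual
        series[cid] = filt
        masks[cid] = premask
    return CleanSegment(
        label=interval.label,
        sampling_rate=fs,
        start_idx=i0,
        channel_ids=list(series),
        series=series,
        mask=masks,
        channels_dropped=dropped,
    )
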