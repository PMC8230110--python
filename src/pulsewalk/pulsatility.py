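"""Cerebral pulse amplitude extraction.

Per rest segment and channel: gate channels on wavelength-coupling quality
(scalp coupling index, SCI) and source-detector separation, detect heartbeat
peaks and flanking diastolic nadirs on the inverted cardiac-band 850 nm
trace (systole increases absorption, so raw intensity dips at systole — the
inversion makes reported amplitudes positive), compute one amplitude per
heartbeat epoch, aggregate per channel with a quantile-robust mean over the
interquartile epochs, and average retained channels into the global
cerebral pulse amplitude.  Heart rate is estimated from the count of valid
beats over the analyzed time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import CleanSegment
from .types import (
    ChannelPulsatility,
    DataError,
    GlobalPulseAmplitude,
    HeartbeatEpoch,
    Montage,
    ParameterError,
)

__all__ = [
    "ExtractionParams",
    "scalp_coupling_index",
    "select_channels",
    "detect_heartbeats",
    "epoch_amplitudes",
    "estimate_heart_rate",
    "channel_pulse_amplitude",
    "global_pulse_amplitude",
    "extract_segment",
]

HR_BOUNDS_BPM = (40.0, 180.0)
EPOCH_DURATION_S = (60.0 / HR_BOUNDS_BPM[1], 60.0 / HR_BOUNDS_BPM[0])


@dataclass
class ExtractionParams:
    """Tunable thresholds of the extraction stage.

    ``nadir_mode='both'`` measures each beat against the mean of the two
    flanking diastolic nadirs; ``'preceding'`` uses only the left one.
    """

    sci_min: float = 0.8
    separation_range_cm: tuple[float, float] = (2.5, 5.6)
    hr_bounds_bpm: tuple[float, float] = HR_BOUNDS_BPM
    prominence_factor: float = 0.3
    quantile_bounds: tuple[float, float] = (25.0, 75.0)
    min_epochs: int = 4
    nadir_mode: str = "both"


def scalp_coupling_index(sig735: np.ndarray, sig850: np.ndarray) -> float:
    """Zero-lag correlation of the z-scored cardiac-band wavelength pair."""
    sig735 = np.asarray(sig735, dtype=float)
    sig850 = np.asarray(sig850, dtype=float)
    if sig735.shape != sig850.shape:
        raise ParameterError("wavelength pair series must have equal length")
    s1, s2 = sig735.std(), sig850.std()
    if s1 == 0 or s2 == 0:
        raise DataError("zero-variance input; SCI undefined")
    z1 = (sig735 - sig735.mean()) / s1
    z2 = (sig850 - sig850.mean()) / s2
    return float(np.mean(z1 * z2))


def select_channels(
    channels: list[ChannelPulsatility],
    sci_min: float = 0.8,
    sep_range: tuple[float, float] = (2.5, 5.6),
) -> tuple[list[ChannelPulsatility], list[ChannelPulsatility]]:
    """Gate 850 nm channels on SCI (inclusive threshold) and separation."""
    retained, dropped = [], []
    for ch in channels:
        reasons = []
        if not np.isfinite(ch.sci) or ch.sci < sci_min:
            reasons.append(f"SCI {ch.sci:.3f} < {sci_min}")
        if not sep_range[0] <= ch.separation <= sep_range[1]:
            reasons.append(f"separation {ch.separation} cm outside {sep_range}")
        if ch.reason:
            reasons.append(ch.reason)
        ch.retained = not reasons
        ch.reason = "; ".join(reasons)
        (retained if ch.retained else dropped).append(ch)
    if not retained:
        raise DataError("no channels retained after SCI/separation gating")
    return retained, dropped


def detect_heartbeats(
    series: np.ndarray,
    fs: float,
    hr_bounds: tuple[float, float] = HR_BOUNDS_BPM,
    prominence_factor: float = 0.3,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Find systolic peaks and diastolic nadirs on an inverted cardiac trace.

    Two-pass adaptive prominence: an unconstrained pass sets the scale
    (median prominence), the second keeps peaks with prominence >=
    ``prominence_factor`` times that median and minimum spacing one beat at
    the upper heart-rate bound.  Peaks inside masked regions are discarded.
    Nadirs are the minima between consecutive peaks plus one before the
    first and one after the last peak.
    """
    series = np.asarray(series, dtype=float)
    min_dist = max(int(round(60.0 / hr_bounds[1] * fs)), 1)
    cand, props = sps.find_peaks(series, distance=min_dist, prominence=0.0)
    if cand.size:
        thresh = prominence_factor * float(np.median(props["prominences"]))
        peaks, _ = sps.find_peaks(series, distance=min_dist, prominence=thresh)
    else:
        peaks = cand
    if mask is not None and peaks.size:
        peaks = peaks[~mask[peaks]]
    if len(peaks) < 3:
        raise DataError(f"only {len(peaks)} heartbeat peaks detected; need >= 3")

    nadirs = []
    first = int(np.argmin(series[: peaks[0]])) if peaks[0] > 0 else 0
    nadirs.append(first)
    for a, b in zip(peaks[:-1], peaks[1:]):
        nadirs.append(a + 1 + int(np.argmin(series[a + 1 : b])))
    tail = series[peaks[-1] + 1 :]
    nadirs.append(peaks[-1] + 1 + int(np.argmin(tail)) if tail.size else len(series) - 1)
    return peaks, np.asarray(nadirs)


def epoch_amplitudes(
    series: np.ndarray,
    peaks: np.ndarray,
    nadirs: np.ndarray,
    fs: float,
    mask: np.ndarray | None = None,
    nadir_mode: str = "both",
) -> list[HeartbeatEpoch]:
    """One amplitude per heartbeat: peak minus mean of flanking nadirs.

    Epochs overlapping an artifact mask or with nadir-to-nadir duration
    outside the physiological beat range are marked invalid.
    """
    series = np.asarray(series, dtype=float)
    epochs = []
    for k, p in enumerate(peaks):
        nl, nr = int(nadirs[k]), int(nadirs[k + 1])
        if nadir_mode == "preceding":
            ref = series[nl]
        else:
            ref = 0.5 * (series[nl] + series[nr])
        amp = float(series[p] - ref)
        dur = (nr - nl) / fs
        valid = True
        reason = ""
        if mask is not None and mask[nl : nr + 1].any():
            valid, reason = False, "overlaps artifact mask"
        elif not EPOCH_DURATION_S[0] <= dur <= EPOCH_DURATION_S[1]:
            valid, reason = False, f"duration {dur:.2f} s outside beat range"
        elif amp < 0:
            valid, reason = False, "negative amplitude"
        epochs.append(
            HeartbeatEpoch(
                peak_idx=int(p),
                nadir_left_idx=nl,
                nadir_right_idx=nr,
                amplitude=amp,
                duration_s=dur,
                valid=valid,
                reason=reason,
            )
        )
    return epochs


def estimate_heart_rate(n_valid_beats: int, analyzed_duration_s: float) -> float:
    """Heart rate (bpm) from the beat count over the analyzed time."""
    if analyzed_duration_s <= 0:
        raise ParameterError("analyzed duration must be > 0")
    return 60.0 * n_valid_beats / analyzed_duration_s


def channel_pulse_amplitude(
    epochs: list[HeartbeatEpoch],
    quantile_bounds: tuple[float, float] = (25.0, 75.0),
    min_epochs: int = 4,
) -> float:
    """Quantile-robust channel amplitude.

    Epoch amplitudes are sorted into quartiles and only the middle two
    (values within [Q25, Q75], inclusive, linear-interpolation percentiles)
    are averaged — robust to occasional noisy beats.
    """
    amps = np.array([e.amplitude for e in epochs if e.valid])
    if len(amps) < min_epochs:
        raise DataError(f"only {len(amps)} valid epochs; need >= {min_epochs}")
    lo, hi = np.percentile(amps, quantile_bounds)
    mid = amps[(amps >= lo) & (amps <= hi)]
    return float(mid.mean())


def global_pulse_amplitude(
    channels: list[ChannelPulsatility],
    participant_id: str = "P00",
    timepoint: str = "T0",
    condition: str = "BW",
    block: int = 1,
) -> GlobalPulseAmplitude:
    """Unweighted mean amplitude over retained channels."""
    retained = [c for c in channels if c.retained]
    if not retained:
        raise DataError("no retained channels; global amplitude undefined")
    return GlobalPulseAmplitude(
        participant_id=participant_id,
        timepoint=timepoint,
        condition=condition,
        block=block,
        value=float(np.mean([c.amplitude for c in retained])),
        n_channels=len(retained),
        heart_rate=float(np.mean([c.heart_rate for c in retained])),
    )


def extract_segment(
    clean: CleanSegment,
    montage: Montage,
    params: ExtractionParams | None = None,
) -> list[ChannelPulsatility]:
    """SCI gating + beat detection + robust amplitude for one rest segment.

    Returns one :class:`ChannelPulsatility` per 850 nm channel whose
    wavelength pair survived preprocessing, with ``retained`` set by the
    SCI/separation gate and epoch sufficiency.
    """
    params = params or ExtractionParams()
    fs = clean.sampling_rate
    results: list[ChannelPulsatility] = []
    for ch735, ch850 in montage.wavelength_pairs():
        if ch850 not in clean.series or ch735 not in clean.series:
            continue
        sep = float(montage.row(ch850)["separation"])
        try:
            sci = scalp_coupling_index(clean.series[ch735], clean.series[ch850])
        except DataError as e:
            results.append(
                ChannelPulsatility(ch850, float("nan"), sep, 0, float("nan"),
                                   float("nan"), False, str(e))
            )
            continue

        amplitude = heart_rate = float("nan")
        n_valid = 0
        reason = ""
        mask = clean.mask[ch850]
        inverted = -clean.series[ch850]
        try:
            peaks, nadirs = detect_heartbeats(
                inverted, fs, params.hr_bounds_bpm, params.prominence_factor, mask
            )
            epochs = epoch_amplitudes(
                inverted, peaks, nadirs, fs, mask, params.nadir_mode
            )
            n_valid = sum(e.valid for e in epochs)
            amplitude = channel_pulse_amplitude(
                epochs, params.quantile_bounds, params.min_epochs
            )
            analyzed_s = (len(inverted) - int(mask.sum())) / fs
            heart_rate = estimate_heart_rate(n_valid, analyzed_s)
        except DataError as e:
            reason = str(e)

        results.append(
            ChannelPulsatility(
                channel_id=ch850,
                sci=sci,
                separation=sep,
                n_epochs=n_valid,
                amplitude=amplitude,
                heart_rate=heart_rate,
                retained=False,
                reason=reason,
            )
        )
    select_channels(results, params.sci_min, params.separation_range_cm)
    return results
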