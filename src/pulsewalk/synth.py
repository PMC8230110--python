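"""Synthetic dual-wavelength NIRS cohort with known ground truth.

The generator emulates the statistical structure the pulsatility analysis
assumes: quasi-periodic cardiac intensity oscillations (~1 Hz with
beat-to-beat variability) riding on slow physiological drifts (Mayer waves
~0.1 Hz, respiration ~0.25 Hz) and detector noise; wavelength pairs whose
cardiac component is shared (good optode coupling) or decoupled (bad
coupling); walking-bout motion artifacts; saturated channels; and a
longitudinal cohort in which before-walking pulse amplitude declines over
12 months of physical activity and that decline correlates with improvement
in Stroop inhibition response time.

Every quantity the pipeline later estimates (per-channel and global
amplitude, heart rate, beat times, coupling class, group effects) is
returned as ground truth alongside the recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    Annotation,
    Montage,
    ParameterError,
    RawNIRSRecording,
)

__all__ = [
    "SignalParams",
    "CohortParams",
    "GroundTruth",
    "default_montage",
    "default_schedule",
    "cardiac_pulse_train",
    "simulate_recording",
    "simulate_cohort",
]

# Cardiac waveform morphology: 3 harmonics with a sharp systolic peak at 20%
# of the cycle, resembling an optical plethysmographic pulse.
DEFAULT_MORPHOLOGY = (1.0, 0.4, 0.15)
SYSTOLIC_PHASE = 0.2

HR_BOUNDS_BPM = (40.0, 180.0)

# Schematic 10-20-flavoured frontal + motor coverage: source, detector,
# label, head-plane (x, y) cm of the channel midpoint, separation cm.
_DEFAULT_PAIRS = [
    ("S1", "D1", "AF7", (-6.0, 7.5), 3.0),
    ("S2", "D2", "AF3", (-3.0, 8.5), 3.0),
    ("S3", "D3", "AFz", (0.0, 9.0), 3.1),
    ("S4", "D4", "AF4", (3.0, 8.5), 3.0),
    ("S5", "D5", "AF8", (6.0, 7.5), 3.0),
    ("S6", "D6", "F5", (-7.0, 4.5), 3.2),
    ("S7", "D7", "Fz", (0.0, 5.0), 3.3),
    ("S8", "D8", "F6", (7.0, 4.5), 3.2),
    ("S9", "D9", "FC3", (-5.0, 2.0), 3.4),
    ("S10", "D10", "FC4", (5.0, 2.0), 3.4),
    ("S11", "D11", "C3", (-6.0, -1.0), 3.5),
    ("S12", "D12", "C4", (6.0, -1.0), 3.5),
]


def default_montage() -> Montage:
    """12 source-detector pairs x 2 wavelengths over prefrontal/motor areas."""
    rows = []
    for src, det, label, (x, y), sep in _DEFAULT_PAIRS:
        for wl in (735, 850):
            rows.append(
                dict(
                    channel_id=f"{src}{det}_{wl}",
                    source_id=src,
                    detector_id=det,
                    wavelength=wl,
                    separation=sep,
                    label=label,
                    x=x,
                    y=y,
                    z=6.0,
                )
            )
    return Montage(pd.DataFrame(rows))


def default_schedule(rest_s: float = 15.0, walk_s: float = 30.0) -> list[Annotation]:
    """Walking-paradigm block: standing rest / walk back-and-forth / rest."""
    return [
        Annotation("BW", 0.0, rest_s),
        Annotation("WALK", rest_s, rest_s + walk_s),
        Annotation("AW", rest_s + walk_s, rest_s + walk_s + rest_s),
    ]


@dataclass
class SignalParams:
    """Parameters of one simulated recording.

    ``pulse_amplitude`` is the per-beat fractional intensity dip at systole
    on the 850 nm channels (scalar for all channels, or a mapping from
    850 nm channel_id to amplitude).  ``coupling`` sets the shared fraction
    of detector-noise variance across the two wavelengths of a pair.
    """

    hr_mean: float = 65.0
    hr_sd: float = 2.5
    pulse_amplitude: float | Mapping[str, float] = 0.61
    wavelength_ratio: float = 0.6
    coupling: float = 0.95
    drift_amp: float = 0.02
    drift_freqs: tuple[float, ...] = (0.1, 0.25)
    noise_sd: float = 0.05
    motion_rate: float = 6.0  # artifacts per minute during WALK
    saturated_channels: tuple[str, ...] = ()
    bad_coupling_channels: tuple[str, ...] = ()  # 850 nm ids of bad pairs
    saturation_ceiling: float = 4096.0
    baseline_level: float = 800.0  # healthy operating point well below ceiling
    sampling_rate: float = 20.0
    montage: Montage = field(default_factory=default_montage)

    def __post_init__(self) -> None:
        if not (HR_BOUNDS_BPM[0] <= self.hr_mean <= HR_BOUNDS_BPM[1]):
            raise ParameterError(f"hr_mean {self.hr_mean} outside {HR_BOUNDS_BPM} bpm")
        if not 0.0 <= self.coupling <= 1.0:
            raise ParameterError("coupling must lie in [0, 1]")
        if any(a < 0 for a in self.amplitude_map().values()):
            raise ParameterError("pulse_amplitude must be >= 0")

    def amplitude_map(self) -> dict[str, float]:
        ids_850 = [c for _, c in self.montage.wavelength_pairs()]
        if isinstance(self.pulse_amplitude, Mapping):
            return {c: float(self.pulse_amplitude[c]) for c in ids_850}
        return {c: float(self.pulse_amplitude) for c in ids_850}


@dataclass
class CohortParams:
    """Planted longitudinal cohort: amplitudes, effects and covariates.

    Defaults encode the study regime: n=19 older adults with cardiovascular
    risk factors; before-walking global amplitude 0.61 +/- 0.07 at baseline
    declining to 0.55 +/- 0.06 after 12 months of physical activity; a
    walk-induced amplitude drop that doubles at 12 months; block-retest
    reliability ~0.85; and a correlation of 0.47 between the amplitude
    decline and the Stroop-inhibition response-time improvement.
    """

    n_participants: int = 19
    amp_bw_t0: tuple[float, float] = (0.61, 0.07)
    amp_bw_t12: tuple[float, float] = (0.55, 0.06)
    walk_effect_t0: float = 0.04
    walk_effect_t12: float = 0.08
    longitudinal_r: float = 0.8
    block_reliability: float = 0.85
    delta_rt_correlation: float = 0.47
    channel_amp_sd: float = 0.03
    aw_extra_sd: float = 0.02
    # Stroop response-time regime: T0 mean/sd per condition, plus the
    # planted 12-month change (mean, sd of within-participant difference).
    stroop_rt_t0: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "naming": (31.52, 7.41),
            "reading": (22.05, 3.68),
            "inhibition": (58.21, 20.57),
            "switching": (63.05, 5.68),
        }
    )
    stroop_rt_delta: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "naming": (-2.42, 8.0),
            "reading": (-0.79, 4.0),
            "inhibition": (-4.16, 6.2),
            "switching": (-6.42, 11.5),
        }
    )
    stroop_error_rate: float = 3.0
    pase: tuple[float, float] = (127.2, 68.5)
    framingham: tuple[float, float] = (12.0, 5.0)
    sbp_t0: tuple[float, float] = (124.57, 13.55)
    sbp_t12: tuple[float, float] = (120.5, 12.09)
    dbp_t0: tuple[float, float] = (75.9, 5.68)
    dbp_t12: tuple[float, float] = (75.88, 6.97)
    signal: SignalParams = field(default_factory=SignalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ParameterError("need at least 3 participants")
        for name in ("amp_bw_t0", "amp_bw_t12"):
            if getattr(self, name)[1] <= 0:
                raise ParameterError(f"{name} sd must be > 0")
        if not abs(self.delta_rt_correlation) < 1:
            raise ParameterError("|delta_rt_correlation| must be < 1")
        if not 0 < self.block_reliability < 1:
            raise ParameterError("block_reliability must lie in (0, 1)")
        # The joint distribution of (amp_T0, amp_T12, delta RT) must be a
        # valid multivariate normal.
        try:
            np.linalg.cholesky(self._correlation_matrix())
        except np.linalg.LinAlgError as e:
            raise ParameterError("infeasible correlation structure") from e

    def _correlation_matrix(self) -> np.ndarray:
        rho, r = self.longitudinal_r, self.delta_rt_correlation
        s0, s12 = self.amp_bw_t0[1], self.amp_bw_t12[1]
        var_d = s0**2 + s12**2 - 2 * rho * s0 * s12
        if var_d <= 0:
            raise ParameterError("infeasible longitudinal correlation")
        sd_d = np.sqrt(var_d)
        c0 = r * (rho * s12 - s0) / sd_d  # corr(amp_T0, delta RT)
        c12 = r * (s12 - rho * s0) / sd_d  # corr(amp_T12, delta RT)
        return np.array([[1.0, rho, c0], [rho, 1.0, c12], [c0, c12, 1.0]])


@dataclass
class GroundTruth:
    """Planted truth for a simulated recording or cohort."""

    amplitudes: pd.DataFrame  # participant, timepoint, condition, block, value
    channel_truth: dict  # (participant, timepoint, block) -> per-channel table
    beat_times: dict  # (participant, timepoint, block) -> systolic times (s)
    deltas: pd.DataFrame | None = None  # per-participant planted deltas
    planted: dict = field(default_factory=dict)


def _waveform_template(morphology: Sequence[float]) -> tuple[np.ndarray, float]:
    """Unit-range single-cycle template on a fine phase grid, and the phase
    (fraction of cycle) of its systolic peak."""
    phi = np.linspace(0.0, 1.0, 2048, endpoint=False)
    w = np.zeros_like(phi)
    for k, a_k in enumerate(morphology, start=1):
        w += a_k * np.cos(2 * np.pi * k * (phi - SYSTOLIC_PHASE))
    w = (w - w.mean()) / (w.max() - w.min())
    return w, phi[int(np.argmax(w))]


def cardiac_pulse_train(
    duration_s: float,
    fs: float,
    hr_mean: float,
    hr_sd: float = 0.0,
    morphology: Sequence[float] = DEFAULT_MORPHOLOGY,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-periodic cardiac waveform with unit per-beat peak-to-trough range.

    Inter-beat intervals are Gaussian around 60/hr_mean with sd derived from
    the beat-to-beat heart-rate sd, truncated to the physiological range
    (40-180 bpm).  Returns ``(waveform, beat_times)`` where ``beat_times``
    are the ground-truth systolic peak times in seconds.

    The waveform is zero-mean with unit peak-to-trough range, so scaling by
    an amplitude ``a`` modulates intensity by ``a`` peak-to-trough without
    shifting the baseline mean; the recording simulator subtracts it from
    baseline intensity (systole increases absorption, so raw intensity dips
    at systole).
    """
    if not (HR_BOUNDS_BPM[0] <= hr_mean <= HR_BOUNDS_BPM[1]):
        raise ParameterError(f"hr_mean {hr_mean} outside {HR_BOUNDS_BPM} bpm")
    if fs <= 2 * (hr_mean / 60.0) * len(morphology):
        raise ParameterError("sampling rate too low for waveform harmonics")
    if duration_s * hr_mean / 60.0 < 2:
        raise ParameterError("duration shorter than two beats")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ibi_mean = 60.0 / hr_mean
    ibi_sd = 60.0 * hr_sd / hr_mean**2
    ibi_lo, ibi_hi = 60.0 / HR_BOUNDS_BPM[1], 60.0 / HR_BOUNDS_BPM[0]

    onsets = [0.0]
    ibis = []
    while onsets[-1] < duration_s:
        ibi = ibi_mean if ibi_sd == 0 else rng.normal(ibi_mean, ibi_sd)
        ibi = float(np.clip(ibi, ibi_lo, ibi_hi))
        ibis.append(ibi)
        onsets.append(onsets[-1] + ibi)
    onsets_arr = np.array(onsets)
    ibis_arr = np.array(ibis)

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    idx = np.searchsorted(onsets_arr, t, side="right") - 1
    phase = (t - onsets_arr[idx]) / ibis_arr[idx]

    template, peak_phase = _waveform_template(morphology)
    wave = np.interp(
        phase % 1.0, np.linspace(0, 1, len(template), endpoint=False), template
    )

    peak_times = onsets_arr[:-1] + peak_phase * ibis_arr
    beat_times = peak_times[(onsets_arr[:-1] < duration_s) & (peak_times < duration_s)]
    return wave, beat_times


def _drift(n: int, fs: float, amp: float, freqs: Sequence[float], rng) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    for f in freqs:
        out += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def _motion_trace(
    n: int,
    fs: float,
    schedule: Sequence[Annotation],
    rate_per_min: float,
    noise_sd: float,
    rng,
) -> np.ndarray:
    """Spikes (0.25-1 s, 10-50x noise) and step shifts during WALK intervals."""
    m = np.zeros(n)
    for ann in schedule:
        if ann.label != "WALK":
            continue
        n_events = rng.poisson(rate_per_min * ann.duration_s / 60.0)
        for _ in range(n_events):
            t0 = rng.uniform(ann.start_s, ann.end_s)
            i0 = int(t0 * fs)
            if rng.random() < 0.7:  # spike
                width = int(rng.uniform(0.25, 1.0) * fs)
                amp = rng.uniform(10, 50) * noise_sd * rng.choice([-1, 1])
                i1 = min(n, i0 + width)
                window = np.hanning(max(2 * (i1 - i0), 2))[: i1 - i0]
                m[i0:i1] += amp * window
            else:  # baseline step, reverts at end of the walk bout
                amp = rng.uniform(5, 20) * noise_sd * rng.choice([-1, 1])
                i1 = min(n, int(ann.end_s * fs))
                m[i0:i1] += amp
    return m


def _accelerometer(
    n: int, fs: float, schedule: Sequence[Annotation], rng
) -> np.ndarray:
    """Rest: gravity + sensor noise.  Walk: ~1.8 Hz gait oscillation."""
    t = np.arange(n) / fs
    accel = rng.normal(0.0, 0.02, size=(3, n))
    accel[2] += 1.0
    for ann in schedule:
        if ann.label != "WALK":
            continue
        sel = (t >= ann.start_s) & (t < ann.end_s)
        gait_f = rng.uniform(1.6, 2.0)
        accel[2, sel] += 0.30 * np.sin(
            2 * np.pi * gait_f * t[sel] + rng.uniform(0, 2 * np.pi)
        )
        accel[0, sel] += rng.normal(0.0, 0.10, size=sel.sum())
        accel[1, sel] += rng.normal(0.0, 0.10, size=sel.sum())
    return accel


def simulate_recording(
    params: SignalParams,
    schedule: Sequence[Annotation] | None = None,
    seed: int | np.random.Generator = 0,
    participant_id: str = "P00",
    timepoint: str = "T0",
    block: int = 1,
    amplitude_aw: Mapping[str, float] | None = None,
) -> tuple[RawNIRSRecording, GroundTruth]:
    """Simulate one walking-paradigm recording.

    Channel model (channel i, baseline B_i):

        I_i(t) = B_i * (1 + drift_i(t) - a_i(t) * pulse(t) + m_i(t) + eps_i(t))

    The 735/850 channels of a well-coupled pair share beat times and a
    ``coupling`` fraction of noise variance; pairs listed in
    ``bad_coupling_channels`` receive an independent, rate-offset cardiac
    train on the 735 nm side so the two wavelengths decorrelate in the
    cardiac band.  Saturated channels are clipped at the detector ceiling.

    When ``amplitude_aw`` is given, the cardiac amplitude ramps linearly
    from the before-walk value to the after-walk value across the WALK
    interval (the walk itself is excluded from analysis downstream).
    """
    schedule = list(schedule) if schedule is not None else default_schedule()
    for ann in schedule:
        if ann.label in ("BW", "AW") and ann.duration_s * params.hr_mean / 60.0 < 2:
            raise ParameterError(f"{ann.label} segment shorter than two beats")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = params.sampling_rate
    duration = max(a.end_s for a in schedule)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    if amplitude_aw is not None:
        walk = next((a for a in schedule if a.label == "WALK"), None)
        if walk is None:
            raise ParameterError("amplitude_aw given but schedule has no WALK")
        blend = np.clip((t - walk.start_s) / walk.duration_s, 0.0, 1.0)
    else:
        blend = np.zeros(n)

    pulse, beat_times = cardiac_pulse_train(
        duration, fs, params.hr_mean, params.hr_sd, seed=rng
    )
    amp_map = params.amplitude_map()
    montage = params.montage
    bad = set(params.bad_coupling_channels)
    saturated = set(params.saturated_channels)

    intensity = np.zeros((montage.n_channels, n))
    ch_rows = []
    for ch735, ch850 in montage.wavelength_pairs():
        a_bw = amp_map[ch850]
        a_aw = float(amplitude_aw[ch850]) if amplitude_aw is not None else a_bw
        a850_t = a_bw + (a_aw - a_bw) * blend
        if ch850 in bad or ch735 in bad:
            pulse735, _ = cardiac_pulse_train(
                duration,
                fs,
                min(params.hr_mean * 1.25, HR_BOUNDS_BPM[1]),
                params.hr_sd,
                seed=rng,
            )
            cls = "bad"
        else:
            pulse735 = pulse
            cls = "good"

        eps_shared = rng.normal(0.0, 1.0, n)
        c = params.coupling
        for cid, a_t, pw in (
            (ch735, params.wavelength_ratio * a850_t, pulse735),
            (ch850, a850_t, pulse),
        ):
            eps = params.noise_sd * (
                np.sqrt(c) * eps_shared + np.sqrt(1 - c) * rng.normal(0.0, 1.0, n)
            )
            drift = _drift(n, fs, params.drift_amp, params.drift_freqs, rng)
            motion = _motion_trace(
                n, fs, schedule, params.motion_rate, params.noise_sd, rng
            )
            if cid in saturated:
                base = params.saturation_ceiling * 1.02
            else:
                base = params.baseline_level * rng.uniform(0.8, 1.2)
            sig = base * (1.0 + drift - a_t * pw + motion + eps)
            idx = montage.channel_ids.index(cid)
            intensity[idx] = np.minimum(sig, params.saturation_ceiling)
        ch_rows.append(
            dict(
                channel_id=ch850,
                pair_735=ch735,
                true_amplitude=a_bw,
                true_amplitude_aw=a_aw,
                coupling_class=cls,
                saturated=(ch850 in saturated),
            )
        )

    rec = RawNIRSRecording(
        sampling_rate=fs,
        intensity=intensity,
        montage=montage,
        accel=_accelerometer(n, fs, schedule, rng),
        annotations=schedule,
        participant_id=participant_id,
        timepoint=timepoint,
        block=block,
        meta={
            "hr_mean": params.hr_mean,
            "saturation_ceiling": params.saturation_ceiling,
        },
    )
    key = (participant_id, timepoint, block)
    ch_tbl = pd.DataFrame(ch_rows)
    truth = GroundTruth(
        amplitudes=pd.DataFrame(
            [
                dict(
                    participant_id=participant_id,
                    timepoint=timepoint,
                    condition="BW",
                    block=block,
                    value=float(ch_tbl["true_amplitude"].mean()),
                )
            ]
        ),
        channel_truth={key: ch_tbl},
        beat_times={key: beat_times},
        planted={"hr_mean": params.hr_mean, "hr_sd": params.hr_sd},
    )
    return rec, truth


def simulate_cohort(
    params: CohortParams, with_recordings: bool = True
) -> tuple[list[RawNIRSRecording], pd.DataFrame, GroundTruth]:
    """Simulate the longitudinal cohort.

    Per participant, (amp_T0, amp_T12) are drawn from a bivariate normal
    with the planted means/sds and between-visit correlation; the Stroop
    inhibition response-time change is constructed to correlate with the
    amplitude change at ``delta_rt_correlation`` in expectation.  Each visit
    has two walking blocks sharing the participant amplitude plus block
    noise sized to the target block reliability; the after-walking amplitude
    is the before-walking amplitude minus the planted walk effect.  Channel
    amplitudes scatter around the block value with sd ``channel_amp_sd``.

    With ``with_recordings=False`` only covariates and ground truth are
    produced (recordings list empty) — used for large-n calibration checks
    of the statistics layer.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    m0, s0 = params.amp_bw_t0
    m12, s12 = params.amp_bw_t12
    rho = params.longitudinal_r

    cov = np.array([[s0**2, rho * s0 * s12], [rho * s0 * s12, s12**2]])
    amps = rng.multivariate_normal([m0, m12], cov, size=n)
    amp_t0, amp_t12 = amps[:, 0], amps[:, 1]
    d_amp = amp_t12 - amp_t0
    var_d = s0**2 + s12**2 - 2 * rho * s0 * s12
    z_d = (d_amp - (m12 - m0)) / np.sqrt(var_d)

    r = params.delta_rt_correlation
    deltas_rt = {}
    for cond, (dm, dsd) in params.stroop_rt_delta.items():
        if cond == "inhibition":
            deltas_rt[cond] = dm + dsd * (
                r * z_d + np.sqrt(1 - r**2) * rng.normal(size=n)
            )
        else:
            deltas_rt[cond] = dm + dsd * rng.normal(size=n)

    pids = [f"P{i:02d}" for i in range(n)]
    cov_rows = []
    for i, pid in enumerate(pids):
        pase0 = float(np.clip(rng.normal(*params.pase), 0, 793))
        fram = float(rng.normal(*params.framingham))
        rt_t0 = {
            c: max(rng.normal(*params.stroop_rt_t0[c]), 1.0)
            for c in params.stroop_rt_t0
        }
        for tp in ("T0", "T12"):
            sbp = rng.normal(*(params.sbp_t0 if tp == "T0" else params.sbp_t12))
            dbp = rng.normal(*(params.dbp_t0 if tp == "T0" else params.dbp_t12))
            row = dict(
                participant_id=pid,
                timepoint=tp,
                pase=pase0 + (0.0 if tp == "T0" else float(rng.normal(0, 15))),
                framingham=fram + (0.0 if tp == "T0" else float(rng.normal(0, 1))),
                sbp=float(sbp),
                dbp=float(dbp),
                pulse_pressure=float(sbp - dbp),
            )
            for c in params.stroop_rt_t0:
                rt = rt_t0[c] if tp == "T0" else max(rt_t0[c] + deltas_rt[c][i], 1.0)
                row[f"stroop_rt_{c}"] = float(rt)
                row[f"stroop_err_{c}"] = int(rng.poisson(params.stroop_error_rate))
            cov_rows.append(row)
    covariates = pd.DataFrame(cov_rows)

    sigma_block = {
        "T0": s0 * np.sqrt(1.0 / params.block_reliability - 1.0),
        "T12": s12 * np.sqrt(1.0 / params.block_reliability - 1.0),
    }
    walk_effect = {"T0": params.walk_effect_t0, "T12": params.walk_effect_t12}
    amp_by_tp = {"T0": amp_t0, "T12": amp_t12}

    truth_rows = []
    recordings: list[RawNIRSRecording] = []
    channel_truth: dict = {}
    beat_times: dict = {}
    seed_seq = np.random.SeedSequence(params.seed)
    ids_850 = [c for _, c in params.signal.montage.wavelength_pairs()]
    n_pairs = len(ids_850)

    for i, pid in enumerate(pids):
        for tp in ("T0", "T12"):
            for blk in (1, 2):
                bw = amp_by_tp[tp][i] + rng.normal(0, sigma_block[tp])
                aw = (
                    amp_by_tp[tp][i]
                    - walk_effect[tp]
                    + rng.normal(0, sigma_block[tp])
                    + rng.normal(0, params.aw_extra_sd)
                )
                bw, aw = max(bw, 1e-3), max(aw, 1e-3)
                truth_rows.append(
                    dict(participant_id=pid, timepoint=tp, condition="BW",
                         block=blk, value=bw)
                )
                truth_rows.append(
                    dict(participant_id=pid, timepoint=tp, condition="AW",
                         block=blk, value=aw)
                )
                if not with_recordings:
                    continue
                rec_rng = np.random.default_rng(seed_seq.spawn(1)[0])
                ch_bw = np.maximum(
                    bw + rec_rng.normal(0, params.channel_amp_sd, n_pairs), 1e-3
                )
                amp_bw_map = dict(zip(ids_850, ch_bw.astype(float)))
                amp_aw_map = {c: max(v + (aw - bw), 1e-3) for c, v in amp_bw_map.items()}
                import dataclasses

                sig_params = dataclasses.replace(
                    params.signal, pulse_amplitude=amp_bw_map
                )
                rec, rec_truth = simulate_recording(
                    sig_params,
                    seed=rec_rng,
                    participant_id=pid,
                    timepoint=tp,
                    block=blk,
                    amplitude_aw=amp_aw_map,
                )
                recordings.append(rec)
                key = (pid, tp, blk)
                channel_truth[key] = rec_truth.channel_truth[key]
                beat_times[key] = rec_truth.beat_times[key]

    delta_tbl = pd.DataFrame(
        dict(
            participant_id=pids,
            amp_bw_t0=amp_t0,
            amp_bw_t12=amp_t12,
            d_amp=d_amp,
            **{f"d_rt_{c}": deltas_rt[c] for c in deltas_rt},
        )
    )
    truth = GroundTruth(
        amplitudes=pd.DataFrame(truth_rows),
        channel_truth=channel_truth,
        beat_times=beat_times,
        deltas=delta_tbl,
        planted=dict(
            delta_rt_correlation=r,
            amp_bw_t0=params.amp_bw_t0,
            amp_bw_t12=params.amp_bw_t12,
            walk_effect=walk_effect,
            block_reliability=params.block_reliability,
        ),
    )
    return recordings, covariates, truth
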