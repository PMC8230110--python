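"""End-to-end orchestration: simulate -> preprocess -> extract -> stats.

`extract_recording` runs the per-recording chain (saturation screen,
segmentation, per-segment cleaning, SCI gating, beat detection, robust
amplitudes) and is the unit the cohort-level driver loops over.
`run_pipeline` executes a full reproducible run from a :class:`RunConfig`,
writing channel/global/participant tables, the statistical summaries and a
run manifest; identical configs produce identical output bytes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import write_covariates, write_table
from .preprocess import Segmentation, clean_segment, drop_saturated_channels, segment_from_accelerometer
from .pulsatility import ExtractionParams, extract_segment, global_pulse_amplitude
from .stats import (
    block_reliability,
    build_participant_table,
    channelwise_contrast,
    delta_correlation,
    paired_ttest,
    residualize,
    stroop_change,
)
from .synth import CohortParams, simulate_cohort
from .types import DataError, GlobalPulseAmplitude, PulsewalkError, RawNIRSRecording

__all__ = ["RunConfig", "extract_recording", "process_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """Complete, serializable configuration of one pipeline run."""

    seed: int = 0
    n_participants: int = 19
    output_dir: str = "results"
    sci_min: float = 0.8
    separation_range_cm: tuple[float, float] = (2.5, 5.6)
    hr_bounds_bpm: tuple[float, float] = (40.0, 180.0)
    quantile_bounds: tuple[float, float] = (25.0, 75.0)
    nadir_mode: str = "both"
    saturation_max_frac: float = 0.01
    alpha: float = 0.05
    q_threshold: float = 0.05
    adjust_covariates: tuple[str, ...] = ()  # e.g. ("pase", "framingham")
    drop_outliers: bool = True

    def extraction_params(self) -> ExtractionParams:
        return ExtractionParams(
            sci_min=self.sci_min,
            separation_range_cm=tuple(self.separation_range_cm),
            hr_bounds_bpm=tuple(self.hr_bounds_bpm),
            quantile_bounds=tuple(self.quantile_bounds),
            nadir_mode=self.nadir_mode,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def extract_recording(
    rec: RawNIRSRecording,
    params: ExtractionParams | None = None,
    saturation_max_frac: float = 0.01,
) -> tuple[dict[str, pd.DataFrame], list[GlobalPulseAmplitude], dict]:
    """Run the full extraction chain on one recording.

    Returns per-condition channel tables (BW/AW), the per-condition global
    amplitudes, and an attrition log (candidate channels -> after
    saturation -> after SCI/separation gating, per condition).
    """
    params = params or ExtractionParams()
    n_candidates = rec.montage.n_channels
    rec_clean, saturated = drop_saturated_channels(rec, max_frac=saturation_max_frac)

    try:
        seg = segment_from_accelerometer(
            rec_clean.accel, rec_clean.sampling_rate, annotations=rec_clean.annotations
        )
    except DataError:
        seg = Segmentation(intervals=list(rec_clean.annotations), source="annotations")

    channel_tables: dict[str, pd.DataFrame] = {}
    globals_list: list[GlobalPulseAmplitude] = []
    attrition = {
        "candidates": n_candidates,
        "after_saturation": rec_clean.montage.n_channels,
        "saturated_channels": saturated,
    }
    for label in ("BW", "AW"):
        try:
            interval = seg.get(label)
        except KeyError:
            continue
        clean = clean_segment(rec_clean, interval)
        channels = extract_segment(clean, rec_clean.montage, params)
        tbl = pd.DataFrame(
            [
                dict(
                    participant_id=rec.participant_id,
                    timepoint=rec.timepoint,
                    block=rec.block,
                    condition=label,
                    channel_id=c.channel_id,
                    sci=c.sci,
                    separation=c.separation,
                    n_epochs=c.n_epochs,
                    amplitude=c.amplitude,
                    heart_rate=c.heart_rate,
                    retained=c.retained,
                    reason=c.reason,
                )
                for c in channels
            ]
        )
        channel_tables[label] = tbl
        globals_list.append(
            global_pulse_amplitude(
                channels,
                participant_id=rec.participant_id,
                timepoint=rec.timepoint,
                condition=label,
                block=rec.block,
            )
        )
        attrition[f"retained_{label}"] = int(tbl["retained"].sum())
    return channel_tables, globals_list, attrition


def process_cohort(
    recordings: list[RawNIRSRecording],
    params: ExtractionParams | None = None,
    saturation_max_frac: float = 0.01,
) -> tuple[pd.DataFrame, list[GlobalPulseAmplitude], list[dict]]:
    """Extract every recording; returns stacked channel table + globals."""
    all_tables = []
    all_globals: list[GlobalPulseAmplitude] = []
    logs = []
    for rec in recordings:
        tables, globs, att = extract_recording(rec, params, saturation_max_frac)
        all_tables.extend(tables.values())
        all_globals.extend(globs)
        logs.append(
            dict(participant_id=rec.participant_id, timepoint=rec.timepoint,
                 block=rec.block, **{k: v for k, v in att.items()
                                     if k != "saturated_channels"})
        )
    channel_table = pd.concat(all_tables, ignore_index=True)
    return channel_table, all_globals, logs


def _channel_matrix(channel_table: pd.DataFrame, timepoint: str, condition: str) -> pd.DataFrame:
    """Participants x channels retained-amplitude matrix (block-averaged)."""
    sel = channel_table[
        (channel_table["timepoint"] == timepoint)
        & (channel_table["condition"] == condition)
        & channel_table["retained"]
    ]
    return sel.pivot_table(index="participant_id", columns="channel_id", values="amplitude")


def run_pipeline(config: RunConfig, cohort: CohortParams | None = None) -> Path:
    """Simulate (or accept) a cohort, extract it, run the statistics.

    Writes to ``config.output_dir``: covariates.csv, channel_pulsatility.csv,
    global_amplitude.csv, participants.csv, contrasts_global.csv,
    contrasts_channels_{bw,aw}.csv, reliability.csv, stroop_change.csv,
    delta_correlation.csv, attrition.csv and manifest.json.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = CohortParams(seed=config.seed, n_participants=config.n_participants)
    recordings, covariates, truth = simulate_cohort(cohort)

    channel_table, globals_list, logs = process_cohort(
        recordings, config.extraction_params(), config.saturation_max_frac
    )
    participants = build_participant_table(globals_list, covariates)

    write_covariates(covariates, out / "covariates.csv")
    write_table(channel_table, out / "channel_pulsatility.csv")
    write_table(
        pd.DataFrame([dataclasses.asdict(g) for g in globals_list]),
        out / "global_amplitude.csv",
    )
    write_table(participants, out / "participants.csv")
    write_table(pd.DataFrame(logs), out / "attrition.csv")

    t0 = participants[participants["timepoint"] == "T0"].set_index("participant_id")
    t12 = participants[participants["timepoint"] == "T12"].set_index("participant_id")
    common = t0.index.intersection(t12.index)
    t0, t12 = t0.loc[common], t12.loc[common]

    # covariate adjustment (own-timepoint covariates), optional
    bw_t0 = t0["bw_mean"].to_numpy()
    bw_t12 = t12["bw_mean"].to_numpy()
    if config.adjust_covariates:
        bw_t0 = residualize(bw_t0, t0[list(config.adjust_covariates)])
        bw_t12 = residualize(bw_t12, t12[list(config.adjust_covariates)])

    contrasts = []
    res = paired_ttest(bw_t0, bw_t12)
    contrasts.append(dict(contrast="BW_T0_vs_BW_T12", t=res.statistic, df=res.df,
                          p=res.p_raw, effect=res.effect, n=res.n))
    for tp, tbl in (("T0", t0), ("T12", t12)):
        r2 = paired_ttest(tbl["bw_mean"].to_numpy(), tbl["aw_mean"].to_numpy())
        contrasts.append(dict(contrast=f"BW_vs_AW_{tp}", t=r2.statistic, df=r2.df,
                              p=r2.p_raw, effect=r2.effect, n=r2.n))
    walk_drop_t0 = t0["bw_mean"].to_numpy() - t0["aw_mean"].to_numpy()
    walk_drop_t12 = t12["bw_mean"].to_numpy() - t12["aw_mean"].to_numpy()
    r3 = paired_ttest(walk_drop_t12, walk_drop_t0)
    contrasts.append(dict(contrast="walk_drop_T12_vs_T0", t=r3.statistic, df=r3.df,
                          p=r3.p_raw, effect=r3.effect, n=r3.n))
    write_table(pd.DataFrame(contrasts), out / "contrasts_global.csv")

    rel_rows = []
    for tp, tbl in (("T0", t0), ("T12", t12)):
        for cond in ("bw", "aw"):
            b1, b2 = f"{cond}_block1", f"{cond}_block2"
            if b1 in tbl and b2 in tbl:
                r, p = block_reliability(tbl[b1].to_numpy(), tbl[b2].to_numpy())
                rel_rows.append(dict(timepoint=tp, condition=cond.upper(), r=r, p=p))
    write_table(pd.DataFrame(rel_rows), out / "reliability.csv")

    rt_cols = [c for c in covariates.columns if c.startswith("stroop_rt_")]
    conds = [c.removeprefix("stroop_rt_") for c in rt_cols]
    cov_t0 = covariates[covariates["timepoint"] == "T0"].set_index("participant_id").loc[common]
    cov_t12 = covariates[covariates["timepoint"] == "T12"].set_index("participant_id").loc[common]
    rt0 = cov_t0[rt_cols].rename(columns=dict(zip(rt_cols, conds)))
    rt12 = cov_t12[rt_cols].rename(columns=dict(zip(rt_cols, conds)))
    err_cols = [f"stroop_err_{c}" for c in conds]
    e0 = cov_t0[err_cols].rename(columns=dict(zip(err_cols, conds)))
    e1 = cov_t12[err_cols].rename(columns=dict(zip(err_cols, conds)))
    stroop = stroop_change(rt0, rt12, e0, e1)
    write_table(stroop, out / "stroop_change.csv")

    d_amp = bw_t12 - bw_t0
    corr_rows = []
    for cond in ("inhibition", "switching"):
        d_rt = (rt12[cond] - rt0[cond]).to_numpy()
        try:
            cres = delta_correlation(d_amp, d_rt, drop_outliers=config.drop_outliers,
                                     alpha=config.alpha)
            corr_rows.append(dict(condition=cond, **{k: v for k, v in cres.items()
                                                     if k != "outliers_removed"},
                                  n_outliers=len(cres["outliers_removed"])))
        except PulsewalkError as e:
            corr_rows.append(dict(condition=cond, r=np.nan, p=np.nan, error=str(e)))
    write_table(pd.DataFrame(corr_rows), out / "delta_correlation.csv")

    for cond in ("BW", "AW"):
        a = _channel_matrix(channel_table, "T0", cond)
        b = _channel_matrix(channel_table, "T12", cond)
        try:
            cmap = channelwise_contrast(a, b, q_threshold=config.q_threshold)
            write_table(cmap, out / f"contrasts_channels_{cond.lower()}.csv")
        except DataError:
            pass

    manifest = dict(
        package="pulsewalk",
        version=__version__,
        config=config.to_dict(),
        cohort_seed=cohort.seed,
        n_recordings=len(recordings),
        outputs=sorted(p.name for p in out.glob("*.csv")),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
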