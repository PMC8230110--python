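"""Longitudinal statistics on the extracted amplitudes.

From results/participants.csv and results/covariates.csv: block-retest
reliability, the paired T0-vs-T12 contrast of before-walking global
amplitude, before-vs-after-walking contrasts at each visit, Stroop change
scores, and the correlation between 12-month amplitude change and Stroop
response-time change (generalized-ESD outlier screen applied).

Run:  python analysis/03_longitudinal_stats.py
"""

import argparse
from pathlib import Path

import pandas as pd

from pulsewalk.stats import (
    block_reliability,
    delta_correlation,
    paired_ttest,
    stroop_change,
)

parser = argparse.ArgumentParser()
parser.add_argument("--results", default="results")
args = parser.parse_args()
out = Path(args.results)

participants = pd.read_csv(out / "participants.csv")
t0 = participants[participants.timepoint == "T0"].set_index("participant_id")
t12 = participants[participants.timepoint == "T12"].set_index("participant_id")
t12 = t12.loc[t0.index]

rows = []
for tp, tbl in (("T0", t0), ("T12", t12)):
    for cond in ("bw", "aw"):
        r, p = block_reliability(tbl[f"{cond}_block1"], tbl[f"{cond}_block2"])
        rows.append(dict(timepoint=tp, condition=cond.upper(), r=r, p=p))
reliability = pd.DataFrame(rows)
reliability.to_csv(out / "reliability.csv", index=False)
print("block-retest reliability:")
print(reliability.to_string(index=False))

contrasts = []
res = paired_ttest(t0.bw_mean.to_numpy(), t12.bw_mean.to_numpy())
contrasts.append(dict(contrast="BW_T0_vs_BW_T12", t=res.statistic, df=res.df,
                      p=res.p_raw, effect=res.effect, n=res.n))
for tp, tbl in (("T0", t0), ("T12", t12)):
    r2 = paired_ttest(tbl.bw_mean.to_numpy(), tbl.aw_mean.to_numpy())
    contrasts.append(dict(contrast=f"BW_vs_AW_{tp}", t=r2.statistic, df=r2.df,
                          p=r2.p_raw, effect=r2.effect, n=r2.n))
r3 = paired_ttest((t12.bw_mean - t12.aw_mean).to_numpy(),
                  (t0.bw_mean - t0.aw_mean).to_numpy())
contrasts.append(dict(contrast="walk_drop_T12_vs_T0", t=r3.statistic, df=r3.df,
                      p=r3.p_raw, effect=r3.effect, n=r3.n))
contrasts = pd.DataFrame(contrasts)
contrasts.to_csv(out / "contrasts_global.csv", index=False)
print("\nglobal paired contrasts:")
print(contrasts.to_string(index=False))

conds = ["naming", "reading", "inhibition", "switching"]
rt0 = t0[[f"stroop_rt_{c}" for c in conds]].rename(columns=lambda c: c.removeprefix("stroop_rt_"))
rt12 = t12[[f"stroop_rt_{c}" for c in conds]].rename(columns=lambda c: c.removeprefix("stroop_rt_"))
e0 = t0[[f"stroop_err_{c}" for c in conds]].rename(columns=lambda c: c.removeprefix("stroop_err_"))
e12 = t12[[f"stroop_err_{c}" for c in conds]].rename(columns=lambda c: c.removeprefix("stroop_err_"))
stroop = stroop_change(rt0, rt12, e0, e12)
stroop.to_csv(out / "stroop_change.csv", index=False)
print("\nStroop change (positive delta_rt = faster at 12 months):")
print(stroop.to_string(index=False))

d_amp = (t12.bw_mean - t0.bw_mean).to_numpy()
corr_rows = []
for cond in ("inhibition", "switching"):
    d_rt = (rt12[cond] - rt0[cond]).to_numpy()
    c = delta_correlation(d_amp, d_rt, drop_outliers=True)
    corr_rows.append(dict(condition=cond, r=c["r"], p=c["p"], n=c["n"],
                          method=c["method"], n_outliers=len(c["outliers_removed"])))
corr = pd.DataFrame(corr_rows)
corr.to_csv(out / "delta_correlation.csv", index=False)
print("\namplitude-change vs RT-change correlation:")
print(corr.to_string(index=False))
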