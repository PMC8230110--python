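"""Channel-wise contrast maps with FDR control.

Paired t-tests per retained channel comparing before-walking amplitude at
T0 versus T12 (and before- versus after-walking at each visit), corrected
across channels with Benjamini-Hochberg FDR; renders each map on the flat
2-D head layout with significant channels ringed.

Run:  python analysis/04_channel_maps.py
"""

import argparse
from pathlib import Path

import pandas as pd

from pulsewalk.plots import plot_channel_map
from pulsewalk.stats import channelwise_contrast
from pulsewalk.synth import default_montage

parser = argparse.ArgumentParser()
parser.add_argument("--results", default="results")
args = parser.parse_args()
out = Path(args.results)

channel_table = pd.read_csv(out / "channel_pulsatility.csv")
montage = default_montage()


def matrix(timepoint: str, condition: str) -> pd.DataFrame:
    sel = channel_table[
        (channel_table.timepoint == timepoint)
        & (channel_table.condition == condition)
        & channel_table.retained
    ]
    return sel.pivot_table(index="participant_id", columns="channel_id",
                           values="amplitude")


maps = {
    "bw_t0_vs_t12": (matrix("T0", "BW"), matrix("T12", "BW")),
    "aw_t0_vs_t12": (matrix("T0", "AW"), matrix("T12", "AW")),
}
for name, (a, b) in maps.items():
    contrast = channelwise_contrast(a, b)
    contrast.to_csv(out / f"contrasts_channels_{name}.csv", index=False)
    fig_path = out / f"channel_map_{name}.png"
    plot_channel_map(contrast, montage, fig_path,
                     title=f"paired t, {name.replace('_', ' ')}")
    print(f"{name}: {int(contrast.significant.sum())}/{len(contrast)} channels "
          f"significant after FDR; map -> {fig_path}")
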