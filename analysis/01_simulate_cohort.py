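"""Simulate the longitudinal walking-paradigm cohort.

Generates the default synthetic cohort (19 older adults, two visits 12
months apart, two walking blocks per visit) and writes the participant
covariates and the planted ground truth under results/.  The raw recording
waveforms are regenerated deterministically from the seed by later steps,
so only the small tables are persisted here.

Run:  python analysis/01_simulate_cohort.py [--seed 42]
"""

import argparse
from pathlib import Path

import numpy as np

from pulsewalk.synth import CohortParams, simulate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out", default="results")
args = parser.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

params = CohortParams(seed=args.seed)
recordings, covariates, truth = simulate_cohort(params)

covariates.to_csv(out / "covariates.csv", index=False)
truth.amplitudes.to_csv(out / "ground_truth_amplitudes.csv", index=False)
truth.deltas.to_csv(out / "ground_truth_deltas.csv", index=False)

bw_t0 = truth.amplitudes.query("timepoint=='T0' and condition=='BW'")["value"]
bw_t12 = truth.amplitudes.query("timepoint=='T12' and condition=='BW'")["value"]
d = truth.deltas
print(f"simulated {len(recordings)} recordings for {params.n_participants} participants")
print(f"planted BW amplitude: T0 {bw_t0.mean():.3f} +/- {bw_t0.std():.3f}, "
      f"T12 {bw_t12.mean():.3f} +/- {bw_t12.std():.3f}")
print(f"planted delta(amplitude)-delta(inhibition RT) correlation: "
      f"{np.corrcoef(d.d_amp, d.d_rt_inhibition)[0, 1]:.3f} "
      f"(target {params.delta_rt_correlation})")
print(f"tables written to {out}/")
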