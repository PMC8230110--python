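# pulsewalk

Cerebral pulse amplitude from dual-wavelength fNIRS, and the longitudinal
statistics linking its change to cognitive change.

Every heartbeat expands the cerebral arterial walls; in continuous-wave
NIRS this appears as a per-beat dip of the detected intensity. The size of
that oscillation — the **cerebral pulse amplitude** — is a proxy of
cerebral arterial stiffness. `pulsewalk` implements the full analysis for
walking-paradigm recordings (standing rest ~15 s, walk ~30 s, standing
rest ~15 s; 735/850 nm, 20 Hz) in older adults followed over 12 months of
physical activity:

- per-segment normalization and zero-phase 0.5–5 Hz cardiac band-pass;
- channel quality control: saturation screen, scalp coupling index
  (zero-lag 735/850 correlation, SCI >= 0.8) and source–detector
  separation gating (2.5–5.6 cm);
- heartbeat peak/nadir detection on the inverted 850 nm trace; per-epoch
  amplitude `peak − ½(nadir_L + nadir_R)`; interquartile-trimmed channel
  mean; global amplitude = mean over retained channels; heart rate from
  beat counts;
- statistics: covariate (PASE/Framingham) residualization, generalized-ESD
  outliers, paired t contrasts (BW T0 vs T12, BW vs AW), block
  reliability, Δamplitude–ΔStroop-RT (partial) correlation, and
  channel-wise paired-t maps with Benjamini–Hochberg FDR;
- a synthetic-cohort generator with full ground truth (planted amplitudes,
  beat times, coupling classes, longitudinal effects), so every stage is
  testable without any data download.

The intended users are researchers processing optical pulsatility
recordings or auditing this class of analysis; all computation lives in
the library (`src/pulsewalk/`), with numbered narrative drivers under
`analysis/` and a `pulsewalk` CLI for shell use.

## Worked example

```bash
python analysis/01_simulate_cohort.py      # cohort + ground truth
python analysis/02_extract_pulsatility.py  # full extraction chain
python analysis/03_longitudinal_stats.py   # contrasts, reliability, Stroop
python analysis/04_channel_maps.py         # FDR channel maps + figures
```

With the default seed the drivers print (abridged):

```
planted BW amplitude: T0 0.606 +/- 0.070, T12 0.527 +/- 0.043
BW T0: recovered 0.6204 +/- 0.0632 (planted draws 0.6061)
BW T12: recovered 0.5457 +/- 0.0402 (planted draws 0.5269)
channels retained: 98.0%

global paired contrasts:
           contrast         t  df            p   effect  n
    BW_T0_vs_BW_T12  6.597961  18 3.390765e-06 0.074684 19
        BW_vs_AW_T0  7.193476  18 1.075450e-06 0.054872 19
       BW_vs_AW_T12 16.524394  18 2.525721e-12 0.069507 19

Stroop change (positive delta_rt = faster at 12 months):
 condition  delta_rt        t        p
inhibition  5.241731 5.048774 0.000084
 switching 11.052453 4.828925 0.000135
```

Reading: the pipeline recovers the planted group decline of before-walking
amplitude (0.62 → 0.55 in normalized-intensity units) and finds it highly
significant in the paired test; the before-vs-after-walking drop is present
at both visits and larger at 12 months; Stroop executive conditions
(inhibition, switching) speed up while naming/reading do not. Single-seed
correlations at n=19 are noisy by nature; the planted Δamplitude–ΔRT
correlation (0.47) is recovered to ±0.05 at n=1000 in the test suite.

The CLI wraps the same stages:

```bash
pulsewalk simulate --seed 3 --n-participants 5 --out sim/
pulsewalk extract sim/P00_T0_block1.tsv --out channels.csv
pulsewalk run --seed 3 --out results/
```

## Layout

```
src/pulsewalk/     io, synth, preprocess, pulsatility, stats, pipeline, plots, cli
analysis/          numbered drivers writing tables under results/
scripts/           acceptance.py
tests/             pytest suite (unit, property, acceptance)
docs/methods.md    model, parameters, calibrations, limitations
```
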