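# Methods

## Scientific background

Each cardiac ejection drives a pressure wave through the cerebral arteries;
the transient arterial-wall expansion raises local (oxy)hemoglobin content
and shows up in continuous-wave NIRS as a per-heartbeat dip in detected
intensity (systole increases absorption). The size of that per-beat
oscillation — the **cerebral pulse amplitude** — behaves as a proxy of
cerebral arterial stiffness: stiffer vessels damp the pulse wave less, so
the optical pulsation is larger. `pulsewalk` extracts this amplitude from
dual-wavelength (735/850 nm) recordings collected around a short
walking bout (stand ~15 s, walk ~30 s, stand ~15 s; two blocks per visit)
and runs the longitudinal statistics relating its 12-month change to
change in Stroop performance in older adults with cardiovascular risk
factors.

Only the 850 nm channels are analyzed for amplitude: arterial blood is
oxyhemoglobin-rich and the 850 nm band is the more sensitive to arterial
pulsation. The 735 nm channel of each optode pair is used for quality
control only.

## Extraction pipeline

Per recording, in order:

1. **Saturation screen.** A channel is dropped when more than `max_frac`
   (default 1%) of samples sit at/above the detector ceiling (taken from
   file metadata, else the per-recording maximum), or when it has zero
   variance. The wavelength partner of a dropped channel is dropped too,
   since an optode pair with one dead wavelength cannot be
   coupling-checked.
2. **Segmentation.** The walking bout is the longest interval where the
   1 s moving sd of the accelerometer magnitude exceeds 3x its standing
   baseline (20th percentile) for at least 5 s; the flanking intervals are
   the before-walking (BW) and after-walking (AW) rests. File annotations,
   when present, take precedence. Only the rests are analyzed.
3. **Per-segment cleaning.** Each channel is divided by its mean over
   artifact-free samples of the segment (gain invariance), band-passed to
   0.5–5 Hz with a 4th-order Butterworth applied forward–backward (zero
   phase, so peak timing is preserved), and demeaned (finite-segment edge
   transients leave a small DC residual after filtering). Motion artifacts
   are flagged where the 0.5 s moving range exceeds 8x a robust sd
   (MAD x 1.4826) of the trace or accelerometer jerk exceeds 8x its robust
   sd, padded by 0.5 s. Masked samples are excluded from normalization
   means; epochs overlapping a mask are discarded rather than corrected.
4. **Channel gating.** The scalp coupling index (SCI) is the zero-lag
   correlation of the z-scored cardiac-band 735/850 traces of a pair.
   Channels are retained when SCI >= 0.8 (inclusive) and source-detector
   separation lies in 2.5–5.6 cm (depth-sensitive to cortex). SCI is
   computed on the same 0.5–5 Hz band as the rest of the pipeline; the
   band is configurable.
5. **Beat detection.** On the *inverted* band-passed 850 nm trace (so the
   systolic peak is positive), peaks are detected with minimum spacing of
   one beat at 180 bpm and a two-pass adaptive prominence threshold
   (0.3 x the median prominence of an unconstrained first pass) — a fully
   automated replacement for interactive peak curation, chosen for
   reproducibility. Diastolic nadirs are the minima between consecutive
   peaks, plus one before the first and after the last peak.
6. **Epoch amplitude.** amplitude = series[peak] − ½(series[left nadir] +
   series[right nadir]). Using both flanking nadirs is the default (a
   single-preceding-nadir mode is available via `nadir_mode`). Epochs
   overlapping a mask, with nadir-to-nadir duration outside 60/180–60/40 s,
   or with negative amplitude are invalid.
7. **Robust channel aggregate.** Valid epoch amplitudes are trimmed to the
   interquartile range ([Q25, Q75], inclusive, linear-interpolation
   percentiles) and averaged; at least 4 valid epochs are required. This
   keeps the estimator stable under up to 25% contaminated epochs.
8. **Global amplitude & heart rate.** The global cerebral pulse amplitude
   is the unweighted mean over retained channels; heart rate is
   60 x (valid beats)/(analyzed unmasked time).

## Statistics

- **Covariate adjustment**: OLS residualization of amplitude on PASE
  and/or Framingham score (own-timepoint covariates; joint OLS by default,
  scale-preserving: residual + grand mean).
- **Outliers**: generalized extreme Studentized deviate (GESD), default
  alpha 0.05, up to ceil(0.1 n) removals.
- **Contrasts**: two-sided paired t-tests (df = n−1) for BW T0 vs T12,
  BW vs AW per visit, and the walk-induced drop T12 vs T0.
- **Reliability**: Pearson correlation between block-1 and block-2 global
  amplitudes.
- **Change–change correlation**: plain Pearson between Δamplitude and
  ΔStroop-RT by default (partial correlation with Δcovariates optional;
  with an empty covariate set the two coincide exactly); GESD screening of
  the deltas reproduces single-outlier exclusion reproducibly.
- **Channel-wise maps**: paired t per channel over the intersection of
  participants with data in both conditions (>= 3 paired rows),
  Benjamini–Hochberg FDR across channels, significance at q < 0.05. BH
  (not BY) because no dependence structure is assumed across this small
  channel set.

## Synthetic cohort

The generator produces recordings with the statistical structure the
pipeline assumes, with full ground truth:

- **Cardiac waveform**: 3 harmonics with weights (1, 0.4, 0.15) aligned at
  a systolic phase of 0.2 of the cycle (PPG-like skew), normalized to zero
  mean and unit peak-to-trough per beat. Inter-beat intervals are Gaussian
  (default 65 ± 2.5 bpm beat-to-beat) truncated to 40–180 bpm.
- **Channel model**: `I(t) = B·(1 + drift − a·pulse(t) + motion + noise)`
  with Mayer-wave (0.1 Hz) and respiratory (0.25 Hz) drifts (2% of
  baseline), white detector noise (5% default), and a per-channel
  amplitude `a`. Wavelength pairs share beat times and a `coupling`
  fraction (default 0.95) of noise variance; the 735 nm amplitude is 0.6x
  the 850 nm one. Baseline sits at ~20% of the detector ceiling so only
  deliberately planted channels saturate.
- **Bad coupling** is modelled as an independent cardiac train on the
  735 nm side whose rate is offset by 25% from the true train. A same-rate
  independent-phase train can stay phase-locked across a 15 s rest, which
  a zero-lag correlation cannot separate; the rate offset makes the
  planted good/bad classes cleanly separable, which is what the
  quality-control check needs to be tested against.
- **Motion**: during the walk, a Poisson stream (6/min) of 0.25–1 s spikes
  (10–50x noise sd) and step baseline shifts; the accelerometer gains a
  ~1.8 Hz gait oscillation.
- **Cohort**: per participant, (BW amplitude T0, T12) are bivariate normal
  with means/sds (0.61, 0.07) and (0.55, 0.06) and between-visit
  correlation 0.8. The correlation is a derived calibration: it is the
  value at which the planted decline is detected at p < 0.001 in >= 80% of
  n=19 repetitions, i.e. the regime in which the longitudinal effect is
  actually significant at that sample size; it is also consistent with the
  within-visit block reliability (~0.85 planted; ~0.7–0.8 after extraction
  noise). Two blocks per visit share the participant amplitude plus block
  noise sized to the planted reliability; AW amplitude is BW minus a walk
  effect (0.04 at T0, 0.08 at T12 — derived calibrations chosen so the
  BW−AW contrasts sit in the reported range, not stated parameters);
  channel amplitudes scatter (sd 0.03) around the block value. The Stroop
  inhibition RT change is constructed to correlate with the amplitude
  change at r = 0.47; per-condition RT change means are the
  study-population values and their sds are derived calibrations that
  reproduce the reported significance pattern (inhibition p ≈ 0.008,
  switching p ≈ 0.025, naming/reading ns). Covariates (PASE, Framingham,
  blood pressures) are drawn at the study-population moments.
- One reported sd is ambiguous in the source descriptives: the 12-month BW
  amplitude sd appears both as 0.06 and 0.12 in different passages; the
  generator uses 0.06.

### What the generator does not emulate

Real optode-scalp physics (photon transport, partial volume), pulse
waveform variability with vascular tone, respiratory modulation of beat
amplitude, gait-synchronous mechanical artifacts in the optical channel
during walking, and drop-out/re-seating of optodes between blocks. Passing
recovery tests therefore demonstrates correctness of the algorithms under
the assumed signal model, not performance on arbitrary real data.

## Numerical choices and known limitations

- Sampling: 20 Hz; the 0.5–5 Hz band keeps the cardiac fundamental and
  2–3 harmonics for heart rates 40–180 bpm (at high heart rates the 3rd
  harmonic is attenuated near the 5 Hz edge; effect on amplitude < a few
  percent).
- Peak/nadir picking on a noisy series selects local extrema of signal +
  noise, giving a small positive amplitude bias (~ +0.4x the in-band noise
  sd; ≈ +2.5% at default cohort settings). The interquartile trim does not
  remove this bias (it is symmetric in rank, the bias is in location). It
  is well inside the 2-SE acceptance band and is reported here rather than
  hidden by tuning.
- The global amplitudes (~0.6) follow the study's printed scale; as
  fractional intensity modulations they would be physiologically large,
  but the scale of the printed values is not further specified at the
  source, so the generator plants them as given and the pipeline reports
  raw normalized-intensity amplitude without rescaling.
- Degenerate inputs: zero-variance channels are dropped with reasons;
  zero-variance paired differences raise a guarded error (except the
  exactly-identical case, reported as t=0, p=1); all-masked segments drop
  the channel.
- Monte-Carlo problem sizes in the tests (cohort reps, seed counts per
  grid cell) are chosen so each check resolves its tolerance with
  comfortable Monte-Carlo error while the whole suite stays quick on one
  CPU; they are stated in the individual tests.
- The per-cohort power and null-calibration checks run at the
  planted-amplitude level (`simulate_cohort(with_recordings=False)`):
  these are properties of the planted regime and the statistics layer,
  while waveform-level extraction fidelity is checked separately on full
  recordings.
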