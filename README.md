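# cordmotion

Quantification of cervical spinal cord motion from cardiac-gated
phase-contrast MRI (PC-MRI), with a synthetic cohort simulator and the
cohort-level statistics used in reliability studies.

The measurement chain mirrors standard clinical practice for slow-flow
PC-MRI velocimetry:

1. **ROI sampling** — mean signed grey value inside a predefined
   ellipsoid cord ROI (30.52 mm², mid-centred in the cord) at each of the
   20 cardiac timepoints (`phase_image_io`).
2. **Velocity conversion** — `v = grey / 4096 * venc` with venc = 2 cm/s;
   positive = cranial (`velocity_pipeline.grey_to_velocity`).
3. **Phase-drift correction** — subtract the waveform mean, under the
   assumption that net cord motion over one cardiac cycle is zero
   (`velocity_pipeline.correct_phase_drift`).
4. **Motion readouts** — amplitude (peak-to-peak), maximum cranial and
   caudal velocities, and displacement, the rectified rectangle-rule AUC
   with step RR/20 (`velocity_pipeline.compute_readouts`).
5. **Cohort statistics** — exclusion filtering, blood-pressure
   derivations (incl. mean arterial pressure), per-segment summaries,
   Friedman intersegment comparisons with Dunn/Bonferroni follow-up,
   two-way mixed-model absolute-agreement average-measures ICC for
   inter-rater and test–retest reliability, and Spearman correlations
   (`cohort_stats`).

`synthetic_cohort` generates phantoms with the full statistical structure
the pipeline assumes — biphasic pulse-synchronous motion template (quiet
first half-cycle, caudal then cranial lobe), per-subject peak draws,
injected phase drift (~0.2–0.3 cm/s), grey-value quantization, and
per-pixel noise — together with exact ground truth, so every stage is
testable without clinical data.

## CLI

```sh
cordmotion simulate --config run.yaml          # synthesize + quantify + report
cordmotion quantify --config run.yaml          # fixture-dir / dicom-dir input
cordmotion report   --config run.yaml          # stats from an existing readouts.csv
cordmotion run      --config run.yaml          # whatever the config's mode says
```

Example `run.yaml`:

```yaml
mode: simulate            # simulate | fixture-dir | dicom-dir | report
seed: 7
output_dir: out
reliability: test_retest  # optional: test_retest | inter_rater
cohort:
  n_subjects: 18
  n_scans: 2
  pixel_noise_sd: 20.0
  drift: [0.25, 0.025]
```

Outputs land in `output_dir`: per-series waveform CSVs, `readouts.csv`
(long format: subject, scan, rater, segment, corrected flag, four
readouts, drift estimate, RR), `segment_summary.csv`,
`intersegment_comparisons.csv`, optional reliability/correlation CSVs,
and `manifest.json` with SHA-256 checksums — identical config + seed
gives identical checksums.

Series are stored either as plain-text fixtures (`*.pcs`: magic line,
JSON header, integer frame block) or as DICOM directories (one
single-frame file per cardiac phase, ordered by TriggerTime).

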