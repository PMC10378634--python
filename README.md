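# protonband

Daily robustness-band assessment for proton head-and-neck treatment plans,
exercised on a fully synthetic phantom cohort.

For each patient the pipeline

1. builds a voxel phantom (targets + organs at risk) and an analytic
   proton-like plan (Gaussian lateral penumbra x modulated depth profile
   with a logistic distal falloff), normalized so each target's nominal
   D95% equals its prescription;
2. enumerates setup/range uncertainty scenarios (by default 7 shift vectors
   x 3 range scales, at 3 mm and 5 mm setup uncertainty with 3.5% range
   uncertainty) and computes the min–max **robustness band** of every
   plan-quality metric (target D95%/V100%, OAR max/mean dose);
3. samples per-fraction 6-DOF setup errors, recomputes each daily
   fraction's metrics, flags values outside the bands, and scores the
   out-of-band excursion — as a percent of prescription for D95%, in
   percentage points of volume for V100%, in Gy for OAR metrics;
4. aggregates per-class/tier summaries and runs the cohort statistics
   (Student's t-tests between patient classes and target tiers, a paired
   one-sided t-test of within-robustness rates between the two setup
   settings, and daily-shift magnitude comparisons).

The default cohort has 6 patients (2 "primary-only"-like with larger daily
shifts, 4 "primary + nodal"-like with an elongated secondary target and
larger rotational errors), 203 fractions in total, on a 44x44x60 grid at
2.5 mm spacing. Everything is deterministic under one root seed.

## Command-line usage

```bash
protonband run -o out/                 # full pipeline on the built-in cohort
protonband run -c run.yaml -o out/ --seed 7 --setup 3 --setup 5
protonband simulate -o fixtures/       # masks, dose grids, shift log only
protonband bands -o out/               # scenario bands only
protonband evaluate -o out/            # per-fraction records
protonband stats -o out/               # summaries + tests from records.csv
protonband import-external fixtures/ -o out2/   # externally supplied grids
protonband default-config run.yaml     # dump the editable default config
```

Outputs: `bands.csv`, `records.csv`, `shifts.csv`, `summaries.csv/json`,
`stats.json`, `metadata.json` (all CSVs carry a `# config_hash=` header),
plus band/deviation figures. With `--export-grids`, per-patient masks
(uint8 NIfTI), per-fraction dose grids (float32 NIfTI, Gy) and plan
metadata are written under `patients/<id>/`; `import-external` consumes the
same layout, so external dose engines can replace the analytic model while
keeping the downstream analysis identical.

## Package layout

| module | contents |
| --- | --- |
| `protonband.synthetic` | phantoms and solid masks, analytic beam/dose model, plan normalization/calibration, 6-DOF shift sampling, cohort configuration and the default cohort |
| `protonband.dvh` | voxel-list DVH metrics (D95%, V100%, Dmax, Dmean) and binned cumulative DVH curves |
| `protonband.bands` | uncertainty scenario enumeration (axes/separate/corners variants), per-scenario metric evaluation, min–max bands, band membership |
| `protonband.deviation` | per-fraction deviation records, dose/volume deviation rules, group summaries |
| `protonband.stats` | Student's t-tests (two-sample pooled, paired one-sided), daily-shift comparisons |
| `protonband.pipeline` / `protonband.cli` / `protonband.io` | orchestration, typer CLI, CSV/NIfTI/JSON I/O with export–import round trips |

## Conventions

* Frame: x = left-right, y = anterior-posterior, z = superior-inferior; mm
  internally everywhere.
* Rotations: intrinsic yaw (z), pitch (x), roll (y) about the plan
  isocenter, degrees in I/O; daily setup errors move the anatomy while
  beams stay fixed.
* D95% interpolates linearly between sorted-voxel order statistics at the
  fractional rank (a nearest-rank option exists); V100% counts voxels with
  dose >= threshold (ties covered); Dmax is the single hottest voxel — no
  clinical volume smoothing.
* Bands use closed intervals: a value exactly on a bound is within
  robustness. Deviations are positive magnitudes, zero inside the band.
* Daily fraction doses are recomputed with range scale 1 (range error is a
  planning uncertainty, not a daily observable).
* Shift magnitude is the Euclidean norm of the translations only.
* Per-patient random substreams come from `SeedSequence([root_seed,
  patient_index])`, so cohorts reproduce regardless of execution order.
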