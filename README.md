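# octhrombus

Depth-resolved attenuation and backscatter analysis of intracoronary
thrombus in intravascular OCT, with red/white discrimination and
observer-agreement statistics — plus a forward phantom simulator so the
whole pipeline is testable without clinical data.

Frames live in the polar domain (rows = A-lines, columns = depth samples,
index 0 at the catheter; depth of sample *j* is `j * axial_pitch_mm`).
Given a frame and a manually traced thrombus ROI, the pipeline:

1. **optics** — estimates a per-pixel attenuation coefficient (mm⁻¹) from
   the ratio of local intensity to the trapezoidal integral of the
   remaining A-line tail (after noise-floor subtraction and a small uniform
   pre-filter), and a log-scale backscatter term from the single-scattering
   model `b = log10(I / (mu * T)) + gain`;
2. **roi_stats** — filters the ROI by a minimum-attenuation threshold
   (default 0.15 mm⁻¹, alternate 0.5 mm⁻¹), summarises attenuation,
   backscatter and grayscale with nine statistics (median, mean, sd,
   skewness, kurtosis, p5/p10/p90/p95), and aggregates frames per patient
   by pixel-count-weighted averaging, including the ratio of
   95th-percentile attenuation to median grayscale;
3. **classify** — maps the six-stage visual grade to binary red/white,
   classifies parameters against a shipped cutoff registry
   (median attenuation < 0.568 mm⁻¹, mean backscatter < 5.35,
   mean grayscale < 120.1, ratio > 0.022 mm⁻¹ ⇒ red), and runs ROC
   analysis with Youden-index cutoffs and DeLong confidence intervals;
4. **agreement** — Bland–Altman limits of agreement, absolute-agreement
   two-way single-measures ICC(A,1), unweighted Cohen's kappa, and
   Spearman correlation;
5. **simulate** — forward phantoms from the same single-scattering physics
   (red thrombus shadows emerge from high attenuation, not painted
   pixels), cohort generation with class-conditional effect sizes, and
   synthetic observer readings.

## CLI

```sh
# simulate a 13-white / 17-red cohort of 3-frame pullbacks
octhrombus simulate --out data/ --seed 7

# per-frame + per-patient statistics at a threshold
octhrombus analyze --in data/ --out results/ --threshold 0.15

# cutoff labels, and (given truth) ROC/Youden per headline parameter
octhrombus classify --patients results/patients.csv --truth data/truth.csv --out roc/

# observer agreement (two summary tables and/or a readings table)
octhrombus agreement --a run1/patients.csv --b run2/patients.csv --out agree.csv
octhrombus agreement --readings data/readings.csv --out kappa.csv

# per-threshold sensitivity/specificity/J table for one parameter
octhrombus roc-table --patients results/patients.csv --truth data/truth.csv \
    --parameter mean_grayscale --out roc_table.csv
```

All commands accept `--config cfg.json` with flag overrides; outputs embed
the config hash and seed, so identical configs reproduce byte-identical
files.

### File formats

* Intensity stacks: multi-page TIFF (8/16-bit or float32) or a directory of
  PNG pages, with a JSON sidecar `{axial_pitch_mm, catheter_offset,
  patient_id, frame_ids}`.
* Masks: single-channel images, multi-page TIFF stacks, or run-length JSON
  `{shape, runs: [[start, length], ...]}` (row-major).
* Statistic tables: tidy CSV with fixed column order
  `patient_id, frame_id, channel, statistic, value, included_pixels,
  threshold_mm`; the per-patient table adds one `ratio /
  att95_over_median_grayscale` row. A leading `# config_hash=... seed=...`
  comment line carries provenance.

## Notes

* Grayscale statistics are computed over the same attenuation-thresholded
  pixel set as the other channels; backscatter values undefined at included
  pixels (at/below the noise floor) are dropped from that channel only.
* The backscatter gain (default 5.0) is an arbitrary offset; absolute scale
  agreement with any particular scanner software is not claimed.
* Scan conversion to Cartesian display coordinates, proprietary raw-data
  parsing, and automatic thrombus segmentation are out of scope.
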