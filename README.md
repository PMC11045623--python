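# atscreen

Unsupervised **automated target screening** for LC- and GC-HRMS data:
annotate, retention-time-correct, and quantify hundreds of targeted analytes
per batch without manual peak review.

Targeted screening with reference standards gives low detection limits and
confident annotation, but the usual vendor-software evaluation is manual and
slow, while feature-finding tools built for non-target screening struggle
with noisy extracted ion chromatograms (EICs), retention-time (RT) drift
between samples, and multi-peak patterns such as co-eluting isomers sharing
one *m/z*. `atscreen` is built for exactly those problematic chromatograms:
it is aimed at environmental chemists, metabolomics labs and anyone running
large target lists against large sample sets who wants screening plus
in-workflow quantification from centroided mzML with no supervision.

## What it does

For each batch (solvent blanks, reference standards, calibration levels, an
optional IS-only control and matrix QCs, plus the samples):

1. **EIC layer** — per target *m/z* ± tolerance (5 ppm default) an EIC is
   extracted, and a 1.5×-extended *background EIC* provides baseline and
   noise. The baseline is the 25% intensity quantile unless any of three
   triggers fires (zigzag fraction ≥ 25%, relative background RMSE ≥ 10%,
   max/Q25 ≤ 3), in which case the 80% quantile is used. Noise is the
   standard deviation of the baseline-defining intensities, and
   `LOD = baseline + 3·noise`, `LOQ = baseline + 10·noise` act as in-sample
   intensity thresholds.
2. **Peak walker** — seeded at the highest intensity in the search window,
   walking both flanks along decreasing intensities. A non-decreasing run is
   tolerated up to 5× the data density (points per 0.1 min); a drop > 40%
   relative to the last assigned intensity continues the peak through bumps;
   a sustained rise > 40% lasting more than ¼ of the data density starts a
   new peak. Where two walks touch, the valley becomes an enforced split
   point — this is what separates galaxolide/tonalide-style pairs with a
   10:1 height ratio on a shared *m/z*. Peak shapes are encoded as SAX
   (symbolic aggregate approximation) letter sequences; MINDIST between SAX
   sequences is an optional shape gate.
3. **Shift model** — the mean displacement of all internal standards gives
   the batch-global shift; the largest displacement (floored at 0.5 min LC /
   0.1 min GC) gives the search half-width. Calibration series are checked
   for intensity-dependent shifts (column overload: higher concentrations
   elute earlier), validated by regression and an IS-only-control veto.
   Each sample's own IS displacement then refines the per-analyte window,
   and a valid peak found exactly at the unshifted expected RT overrides a
   computed shift.
4. **Screening** — a candidate peak is `DETECTED` if it clears four gates:
   residual shift, shape (optional), ≥ 7 data points, and confirming ion
   present whenever its expected intensity (quantifier height × expected
   ratio, ±20% tolerance) exceeds the confirming ion's own LOD. Failing a
   gate yields `CHECK` (area integrated, counted negative in unsupervised
   mode); no candidate yields `NOT_DETECTED`.
5. **Quantification** — blank masking (responses in > ⅓ of blanks: subtract
   the blank mean, mask samples ≤ 3× it), matrix correction from QC medians,
   IQR validation of constant-concentration references, and a six-variant
   auto-trimmed linear calibration: {through origin, free intercept} ×
   {unweighted, w = x, w = 1/x}, trimmed by Cook's distance while the median
   quantification error `median(|(C_actual − C_predicted)/C_actual|·100)`
   drops and R² rises (≥ 4 points kept). Variants need R² ≥ 0.95 and error
   < 30%; the winner has the lowest error, widest retained range, highest
   R². Concentrations, recoveries (vs. the median valid reference response
   ratio) and a TRUE/FALSE/masked matrix come out as CSV tables.

A seeded synthetic-batch generator (`atscreen.synth`) writes standard mzML
with full ground truth (presence, concentrations, shifts) and backs the
entire test suite.

## Worked example

```
$ ats synth --seed 4 --n-analytes 6 --n-samples 3 --out demo/batch
wrote synthetic batch (6 analytes, 3 samples) to demo/batch

$ ats run --manifest demo/batch/manifest.csv --targets demo/batch/targets.csv \
          --is-list demo/batch/internal_standards.csv --out demo/out
screened 6 analytes in 18 samples: 59 detections; outputs in demo/out

$ ats metrics --hits demo/out/screening_hits.csv --truth demo/batch/truth_presence.csv
{"TP": 59, "TN": 37, "FP": 0, "FN": 12, "sensitivity": 0.83, "specificity": 1.0, "accuracy": 0.89}
```

The batch is 18 mzML files (3 blanks, 8 calibration levels spanning
0.1–1000 ng/mL, 3 references, an IS-only control, 3 samples). All planted
sample peaks are found with no false positives. The 12 "misses" are the two
lowest calibration levels of each analyte: with the default
`minimum_cutoff_intensity_factor` of 0.001, peaks below 0.001× the highest
reference height (here the 1000 ng/mL standard) are excluded from peak
selection — the same behaviour that keeps fluctuating low-intensity noise
out of real screens. `demo/out/` additionally holds the response, response-
ratio, concentration and consensus-peak tables plus the qualitative matrix.

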