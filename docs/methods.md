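# Methods

This note documents the models, conventions and numerical choices behind
`atscreen`, and what the synthetic validation does and does not show.

## Signal model and EIC conventions

All retention times are minutes; indices are 0-based; window bounds are
inclusive. An EIC carries one point per MS1 scan inside its window — scans
without a matching centroid contribute an explicit zero, so point counts
reflect the acquisition rate and the *data density* statistic (median count
of points in a half-open 0.1-min window anchored at each point) measures the
true sampling rate. Centroids within the m/z tolerance (5 ppm default;
absolute Da via `mz_tol_is_da`) are **summed**, not maximised: summing is
robust when a centroider splits one ion into two adjacent centroids.

Smoothing (linear interpolation onto half the native spacing followed by a
5-point centred moving average) exists only for shape-dependent operations.
Smoothed traces carry an `is_smoothed` flag and the quantitative operations
(height, trapezoidal area) refuse them outright — a deliberate hard
contract, since silent use of interpolated intensities would bias areas.

### mzML I/O

The reader (`mzml_io.py`) is a small streaming parser (lxml `iterparse`)
covering the subset of mzML this workflow consumes: MS level,
centroid/profile flag, scan start time (minute or second units), and 32/64-
bit float m/z and intensity arrays, zlib-compressed or plain. The
synthetic-fixture writer emits the same subset; round-trips are verified in
the test suite both internally and against an independent reader
(Bioconductor's mzR) to guard against a self-consistent-but-wrong encoding.

## Baseline cascade

The background EIC (window widened 1.5×, clipped to the acquisition range)
feeds the baseline estimate. Quantiles use linear interpolation between
order statistics (numpy default). The three triggers are evaluated with a
provisional baseline/noise taken from the 25% quantile set:

- **zigzag**: fraction of points in alternating-spike runs must stay below
  0.25. Operationally, a point is an alternation candidate if it exceeds
  baseline + 3·noise while both neighbours sit at or below baseline +
  noise, or the mirror case; maximal candidate runs spanning ≥ 4 points
  (candidates plus bracketing neighbours) are flagged. The run-length and
  thresholds are package choices (config-exposed) — only the verbal pattern
  is prescribed.
- **relative RMSE**: RMSE of the baseline-defining intensities about the
  baseline value, divided by the baseline, must stay below 0.10. The
  reference point of this RMSE is a package choice; dividing by the
  baseline makes the trigger scale-free.
- **ratio**: max intensity / 25% quantile must exceed 3. A zero quantile
  (blank region) counts as a failed trigger rather than dividing by zero.

Noise is the *population* standard deviation of the baseline-defining set.
LOD/LOQ (baseline + 3·noise / + 10·noise) are intensity acceptance
thresholds only; no concentration claim is attached to them.

## Peak walker

Bilateral walk from each summit, highest first. Summits are the local
maxima of the raw trace above the seeding floor (the in-sample LOD);
maxima already absorbed by an earlier walk (shoulder bumps) do not seed
again, but genuinely distinct summits do, and their walks may meet — the
contact valley then becomes an enforced split boundary shared by both
peaks. Key numeric conventions:

- plateau tolerance: ceil(5 × data density) points; the 40% decrease rule
  is relative (`new < 0.6 × last assigned`).
- new-peak rule: once a value exceeds 1.4× the last assigned intensity
  while the signal has been rising for more than ceil(¼ × density)
  consecutive points, the walk stops at its last assigned bound. Counting
  the rising run (rather than only points individually above 1.4×) is
  essential: for realistic merged pairs the valley-to-apex ratio rarely
  stays above 1.4 for several consecutive points, yet the second peak is
  plainly there.
- apex localisation is treated as a *shape* decision: the apex index is the
  argmax of a 5-point moving average, refined by the vertex of a local
  quadratic fit over ±4 raw points, because the raw argmax wanders ±2–3
  scans under realistic noise. The reported height is still the raw
  intensity at that index, keeping the quantitative contract.
- peaks below the intensity cutoff (0.001 × highest reference height)
  bypass splitting and tolerate fluctuating shapes; peak selection requires
  height ≥ max(cutoff, LOD) and takes the candidate nearest the expected
  RT, ties to the higher peak.

A geometric fact worth recording: two Gaussians whose apexes are exactly
2σ apart sum to a *unimodal* curve for every height ratio — no valley
exists to split at. Merged-pair validation therefore uses 3σ separation,
the closest spacing with a genuine valley, with height ratios ≥ 0.85 so the
valley-to-apex rise exceeds the 40% trigger.

## Shift model

Three levels, combined additively:

1. **Global**: mean displacement of all detected IS across IS-containing
   samples, computed against the *listed* IS retention times; the search
   half-width is the largest absolute displacement, floored at 0.5 min (LC)
   or 0.1 min (GC). The mean centres the annotation window; the max sizes
   it.
2. **Intensity-dependent**: apex RT regressed on log10(apex height) over
   the calibration levels (log-height rather than concentration, since
   overload displacement scales with response magnitude). Accepted only for
   negative slope with p < 0.05 *and* a clean IS-only control (no peak
   above LOD in the analyte window); without a control the veto is
   unavailable and p < 0.01 is required.
3. **Per-sample**: each sample's IS displacement is stored *relative to the
   reference frame* in which the consensus peak was measured, so the
   consensus RT plus the residual gives the per-sample expectation and a
   missing IS cleanly degrades to the batch-level expectation.

A valid peak at the unshifted consensus RT (within 1 scan spacing,
config-exposed) overrides any computed shift — high-resolution extraction
makes such an exact match distinctive.

## Screening gates and consensus

The consensus peak takes medians (apex RT, flank widths) over reference
detections, the outermost bounds as its RT range, and the SAX shape from
the highest reference. The residual-shift gate uses
max(consensus width, mode floor) as tolerance. The MINDIST shape gate is
off by default (as in routine use); when on, peaks with significant
intensity (≥ LOD) within one consensus width of the expected RT are exempt
from the shape penalty, so distorted-but-present peaks are not lost.
Confirming-ion logic normalises the ratio as confirming/quantifier and
requires co-elution (confirming apex inside the quantifier bounds).

## Calibration

Weighted least squares in six variants; weights `w = x` and `w = 1/x` use
the nominal concentration x. Fits are computed as whitened ordinary least
squares (identical estimator) so Cook's distance comes from the standard
influence machinery for through-origin and free-intercept designs alike.
R² for through-origin variants is the uncentered coefficient of
determination. Trimming always nominates the current max-Cook's-distance
level and keeps the removal only if the quantification error decreases
*and* R² increases with ≥ 4 points retained; the error is recomputed on the
retained points each iteration. The retained extremes define the
quantifiable range (`x_cutoff`/`x_max` on response ratio, `y_cutoff` on
concentration); order of corrections is blank subtraction → response ratio
→ matrix correction → fit. The IQR fence for reference validation is the
conventional 1.5×.

## Synthetic data: what it emulates, and what it does not

The generator plants Gaussian (optionally exponentially tailed) peaks with
linear response–concentration relations, constant-height internal
standards, additive baseline plus Gaussian (optionally heteroscedastic)
noise, alternating-spike interference, co-eluting isomers on shared m/z,
blank contamination, saturation caps, per-sample and batch RT shifts, and
per-compound displacement of the *listed* retention times in −1.1…−0.9 min
(analytes and IS alike, from a dedicated RNG stream so displaced and exact
batches carry byte-identical signal). Signal-to-noise is specified in the
chromatographic convention S/N = 2H / (peak-to-peak noise) with the usual
5σ peak-to-peak span, i.e. S/N = 10 means noise σ = H/25.

Not emulated: mass-spectral fine structure (isotope patterns,
fragmentation), centroider artefacts, correlated (pink) baseline drift,
carry-over between injections, and real matrix chemistry. Passing the
synthetic suite therefore demonstrates the *algorithmic* correctness of
detection, shift correction and calibration under controlled violations —
it does not certify performance on any particular instrument or matrix.

## Problem sizes

The validation experiments use 200 traces for apex/area recovery, 50 merged
pairs, 10 IS × 8 samples for shift recovery, 20 calibration lines, an
8-analyte × 3-sample batch for the shifted-list comparison and a 40-analyte
× 8-sample batch (23 mzML files) for the end-to-end screen — sizes chosen
so the full suite and the reproduction script each finish in about a minute
on a single CPU while keeping every estimate's sampling error well inside
the asserted margins.

## Known limitations

- Linear calibration only; quadratic or segmented ranges are out of scope.
- The MINDIST acceptance ceiling has no published value; the default (3.0)
  is conservative and the gate ships disabled.
- Nonlinear RT warping across a run (LOESS-style alignment) is not
  modelled; the shift model is piecewise-constant per sample.
- Profile-mode data must be centroided upstream; the reader rejects it.
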