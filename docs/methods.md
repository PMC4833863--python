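# Methods

This note records the models behind each pipeline, the conventions that
required a decision, and what the synthetic generators do and do not
emulate.

## Invasion quantification

A 3D invasion assay images a fluorescent cell layer at the bottom of a
collagen-filled well, acquiring a confocal stack upward into the collagen
(z = 0 at the well bottom; the default phantom covers 150 µm as 50 slices of
3 µm). The readout is purely intensity-based:

1. **Threshold subtraction.** The Otsu threshold of the full-stack histogram
   is *subtracted* from every voxel (clipping at 0), not used for
   binarization: background is removed while bright voxels keep their
   relative weight. The histogram uses 256 equal-width bins over
   [min, max]; the returned threshold is the interior bin edge maximizing
   between-class variance, ties broken toward the lowest edge. By default
   the threshold is computed per image; a per-plate pooled threshold is
   available (`per_plate_otsu`).
2. **Z-profile.** Intensity is summed over x and y per slice. This conserves
   total intensity exactly.
3. **Maxima alignment.** Profiles of a plate are co-aligned by padding
   leading zeros so every argmax sits at the largest original argmax
   (trailing zeros equalize lengths). This corrects for variation of the
   cell-layer position between wells. Argmax ties break toward the lowest z
   (the cell layer is nearest the bottom). Alignment is idempotent and
   shifted copies of one profile superimpose exactly.
4. **Invasion horizon.** The original procedure picks the horizon by
   inspecting the collected profiles; here it is an explicit, recorded rule:
   `fixed:K` (default K = 5 slices above the shared maximum) or `frac:F`
   (first slice above the maximum where the mean profile drops below F of
   its peak). The rule and parameters are stored in the output metadata.
5. **Invasion value.** The proportion of a profile's total intensity at
   z *strictly greater* than the horizon ("beyond" = farther from the well
   bottom). Always in [0, 1].
6. **Group test.** One-way fixed-effects ANOVA across condition groups,
   F = MS_between / MS_within on (k−1, N−k) df. Degenerate cases are
   explicit: no between-group variance → F = 0, p = 1; zero within-group
   variance with unequal means → p = 0, flagged.

### Invasion phantom

Cells are isotropic 3D Gaussian blobs of equal amplitude (default
σ_xy = 1.5, σ_z = 1.2 voxels, amplitude 100). A fraction `invaded_fraction`
of the `n_cells` (default 80) is displaced above the monolayer by a
truncated-normal depth (default 60 ± 15 µm, clipped so invaded blobs sit
clearly above the monolayer and inside the stack); the rest sit exactly at
`monolayer_z`. Because a confluent monolayer is a non-overlapping cell
sheet, lateral positions are drawn on a jittered grid that keeps blob
supports disjoint; this also makes threshold subtraction remove the same
mass fraction from every blob, so the invaded/total intensity ratio is
preserved through the pipeline (recovery error < 0.01 across the full
invasion range). The generator returns the rendered invaded-blob mass over
total blob mass as the ground truth, which matches `invaded_fraction` up to
the 1/n_cells granularity of whole-cell assignment.

Background noise is additive Gaussian clipped at zero (default σ = 2;
Poisson shot noise available). Stacks are float32 and round-trip exactly
through multi-page TIFF.

**Anchoring caveat.** The maxima-alignment rule presumes every image has its
profile maximum at the cell layer — true of the real assay, where the
monolayer dominates. A phantom with `invaded_fraction = 1` has no monolayer,
so no alignment rule can find the layer plane from that image alone; the
recovery validation therefore anchors the horizon at the phantom's known
monolayer plane (the operationalized version of the by-inspection choice),
which coincides with the `fixed:5` rule whenever the monolayer holds the
maximum.

## Migration tracks

Tracks are ordered (t, x, y) positions at a fixed frame interval (nominal
10 min, 18 h of imaging, 90 cells per condition). Metrics per cell:

- **Mean speed** = total path length / total elapsed time (per-step
  instantaneous speeds are also exported). Invariant under rigid motions.
- **Directionality ratio** = |end − start| / Σ|step| ∈ [0, 1]; equals 1 only
  for a straight co-directional track.
- **Wound persistence** = mean cosine of the angle between each nonzero step
  and the wound normal, in [−1, 1]. Two candidate persistence metrics are
  deliberately provided (ratio and cosine); reports state which is used.

Group summaries use the box-and-whisker convention with *adjacent-value*
whiskers: the upper adjacent value is the largest observation ≤ Q3 + 1.5·IQR
and the lower adjacent the smallest observation ≥ Q1 − 1.5·IQR. Quartiles
are linear-interpolation ("type 7") order statistics — documented because
the adjacent values depend on it. With that convention the adjacent values
can, for pathological small samples (e.g. {0, 0, 0, 1}), fall inside the
box; they are nevertheless always actual observations, never interpolated
fences.

Group comparison: omnibus one-way ANOVA plus two-sided pooled-variance t
contrasts of each group against the reference condition, Holm-adjusted.

### Persistent-random-walk generator

Each cell takes steps of constant length `speed·dt` with heading increments
drawn N(0, 2·dt/P), so the directional autocorrelation decays as
exp(−t/P) with P = `persistence_time` — the standard definition of the
directional correlation time (the variance is what makes the time constant
equal P rather than 2P). `persistence_time = ∞` gives ballistic tracks with
directionality ratio exactly 1. An optional wound bias renormalizes the mix
`(1−b)·heading + b·wound_axis`, keeping step length constant; `b = 1` moves
cells straight toward the wound. The constant step length means per-cell
mean speed equals the generating speed exactly; real tracks have speed
fluctuations this model does not emulate.

## qPCR kinetics

Relative expression uses the comparative-Ct method with amplification
efficiency fixed at 2 (configurable): ΔCt = mean target Ct − mean reference
Ct per sample, value = 2^−(ΔCt_sample − ΔCt_calibrator); the calibrator is 1
exactly, and adding a constant to a sample's target and reference Ct
simultaneously changes nothing. Replicates aggregate by arithmetic mean on
the Ct scale, equivalently geometric mean on the linear scale — Ct is the
measured quantity, and its noise is approximately Gaussian in cycles.

Decay courses normalize expression to the t = 0 point. The half-life fit is
OLS of ln(expression) on time (k = −slope, t½ = ln 2/k, with stderr and R²);
a nonlinear exponential fit is provided as a cross-check and agrees with the
log-linear fit on clean data. A fitted k ≤ 0 is flagged "no measurable
decay" with infinite half-life rather than an error. Equality of decay
slopes across conditions is tested by the interaction F test in a pooled
log-linear model.

The generator writes Ct tables directly: target Ct rises one cycle per
half-life (expression halves), the reference gene is constant, and Gaussian
noise with default σ = 0.1 cycles is applied on the cycle scale. Default
course: 6 timepoints over 8 h, triplicates, true t½ = 2 h. It does not
emulate efficiency differences between primers or plate effects.

## Survival analysis

The cohort is split at the sample median of the marker (linear-interpolation
median; strictly above → "high", ties go low, so "high" means strictly
above the cutoff). A mean split is available because published descriptions
of this analysis sometimes state the mean; the split statistic is recorded
in the output.

- **Kaplan–Meier**: product-limit estimator; a censored observation tied
  with an event time is still at risk at that time (event counted first).
  With no censoring the estimate equals the empirical survival function.
- **Log-rank**: Mantel–Haenszel form — at each distinct event time the
  observed minus hypergeometric-expected events in the high group, summed,
  squared, over the summed variance; p from χ²(1). Zero total variance is
  flagged degenerate. The statistic is invariant to monotone time
  transforms and to group relabelling.
- **Hazard ratio**: HR = (O_high/E_high)/(O_low/E_low), the
  observed-over-expected ratio matched to the log-rank quantities, rather
  than a Cox regression (a proportional-hazards fit can be used as an
  external cross-check). The 95 % CI uses se(log HR) = √(1/E_high + 1/E_low),
  the standard variance approximation for the O/E-ratio estimator; simulated
  coverage at the default cohort size is ~95 %. Zero events in a group give
  HR 0 or ∞ with a degeneracy flag.

The generator draws exponential event times with group hazards
(baseline, baseline·HR), independent exponential censoring (defaults:
n = 720, baseline hazard 0.1, censoring rate 0.05, true HR 0.5), and marker
values from two Gaussians separated by 6 SD so the median split recovers the
latent groups essentially perfectly. Real cohorts violate all of this —
non-exponential hazards, informative censoring, markers only weakly linked
to the latent risk groups — so passing recovery tests shows the estimator
chain is correct, not that median splits are a good biomarker analysis.

## Problem sizes and numerical choices

Validation runs use the study-scale defaults: 90 cells × 108 ten-minute
intervals for tracks; 80-cell 192×192×50 phantoms; 200 simulated chases for
the half-life distribution; 500 cohorts of 720 patients for hazard-ratio
recovery and CI coverage; 1000 histograms for the Otsu/exhaustive-search
equivalence; 1000 null simulations for the empirical ANOVA size.

All generators take a `numpy` integer seed and are bit-reproducible. JSON
outputs are written with sorted keys and tables with a fixed float format,
so CLI reruns are byte-identical. All z indices are 0-based; "beyond the
horizon" is the half-open range (horizon, nz).

## Known limitations

- No microscope optics: no PSF, no depth-dependent attenuation, no
  refractive-index effects in the phantom; no wound-geometry images (only
  directional track bias).
- The invasion pipeline cannot anchor its horizon on an image whose profile
  maximum is not the cell layer (see the anchoring caveat above).
- No image-based cell tracking, track linking or drift correction; tracker
  output tables are the interface.
- No primer-efficiency estimation from dilution curves; no absolute qPCR
  quantification.
- No stratified or multivariable survival models; no external database
  retrieval.
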