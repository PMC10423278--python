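# Methods

This note documents the models, conventions, defaults and known limitations
of the `dcip` package: what each stage computes, which choices were open and
how they were made, and what the synthetic data can and cannot establish
about real acquisitions.

## The measurement model

A field of view is a `(z, y, x, channel)` voxel volume with channel roles
`mCherry` (nuclear sensor expression), `sfGFP` (delivered complementation),
`autofluorescence` (chloroplasts, far-red) and optionally `BFP`. All voxel
indexing is 0-based `(z, y, x)`; physical voxel size is anisotropic, z
coarser than x/y, in micrometers.

Per nucleus the pipeline reports the mean mCherry and mean (chloroplast-
masked) sfGFP intensity over the 2-D footprint of the object's
maximum-intensity projection, and their quotient, the green/red ratio. The
ratio cancels per-cell sensor expression: it is invariant to a common
positive rescaling of both channels and linear in a rescaling of sfGFP
alone.

## Segmentation

* **Nuclei.** Each z-slice of the mCherry channel is rescaled to a 256-bin
  histogram over its own min–max range and thresholded with Otsu's
  between-class-variance criterion (first-maximum tie-break, so the result
  is deterministic). The binary slices are stacked and connected components
  are labelled in 3-D with 26-connectivity by default, so one nucleus
  detected on several slices becomes one object. Whether 2-D detections
  should be linked across z was an open choice; 3-D linking is the default
  because the readout is per nucleus, and a per-slice object mode
  (`link_z=False`) is kept for fidelity experiments. Components outside
  `[min_voxels, max_voxels]` (default 20 / unbounded) are discarded;
  survivors are relabelled 1..n in raster-scan order. No declumping or
  watershed is applied: touching nuclei merge into one object, which is
  logged. Border objects are kept.
* **Threshold floor.** Plain per-slice Otsu always splits a slice in two; a
  slice containing only detector noise would have ~half its pixels marked
  foreground and weld all objects together. Every per-slice threshold is
  therefore clipped from below by `floor_factor` (default 0.5) times the
  global Otsu threshold of the whole channel (`threshold_floor="auto"`;
  settable to a constant or disabled). This plays the role of the lower
  threshold bound common in cell-image analysis tools.
* **Chloroplasts.** The autofluorescence channel is thresholded the same
  way, and the mask is dilated by 1 voxel (full 26-neighbourhood, config
  `chloro_dilation`) to cover bleed-through halos. Masked voxels are flagged
  *missing* (NaN) for all sfGFP statistics — never zero-filled, which would
  bias projections — so arbitrary intensity changes inside the mask cannot
  affect any nucleus record. A stack without an autofluorescence channel
  disables masking with a warning.
* **Known limitation.** Two-class Otsu on a background-dominated slice can
  place the cut *between* two foreground brightness classes: a dim nucleus
  sharing a slice with a much brighter one is occasionally lost. This is
  intrinsic to the method; the size filter and 3-D linking mitigate but do
  not remove it.

## Quantification

The per-object MIP is restricted to the object's own labelled voxels: each
(y, x) column takes the maximum over that object's z-extent, per channel,
with masked sfGFP voxels excluded from the maximum. Restricting to the
object prevents an unrelated bright structure above or below a nucleus from
contaminating it; a whole-column mode (`whole_column=True`) is available
since either reading of "projection of identified nuclei" is defensible.
Means (not medians or integrated intensities) over the footprint are used,
matching common per-object intensity defaults; no background subtraction is
applied — the ratio normalization is the control for expression
variability. Objects whose footprint has no unmasked sfGFP pixel, or whose
mean red is non-positive, are flagged invalid and excluded from scoring.

Profile plots are smoothed with a centered moving mean of width 3
(shrink-to-valid windows at the edges: the end points average 2 values) and
normalized to the maximum smoothed value; an all-zero profile returns zeros
with a warning rather than dividing.

## Scoring

"A one-tailed 99% confidence bound above the control mean ratio" admits two
readings. The default is a bound on the per-nucleus ratio *distribution*,
`mean + z(0.99) · sd`: with the large control samples this assay produces, a
standard-error bound (`mean + z · sd/√n`, `mode="sem"`) collapses onto the
control mean and would flag essentially every nucleus, contradicting the low
false-positive behaviour the threshold exists to provide. Both modes and a
Student-t variant (`use_t=True`) are implemented and the active choice is
always logged. Under Gaussian null ratios the default bound flags ≈1% of an
independent null sample — verified by Monte Carlo in the acceptance suite.

Positivity is strict (`ratio > threshold`; a tie is negative). Replicate
(plant) summaries pool all fields of view of that plant before counting —
pooling commutes with concatenation, which is tested. Normalized efficiency
(and intensity) divide a replicate's percent positive (mean ratio) by the
same plant's reference-treatment value, so the reference maps to exactly
1.0; replicates with a zero or missing reference are excluded with a
warning, and omitting the reference omits the columns entirely rather than
silently mis-normalizing. `normalize_to_reference_mean` provides the
analogous division-by-reference-group-mean used for densitometry time
courses. The control group for each experiment is named explicitly in the
design — it is never guessed.

## Statistics

All tests run on replicate-level values (e.g. per-plant percent positive),
never pooled nuclei. The Kruskal–Wallis H uses the tie-corrected rank
formula; when every observation ties, the correction degenerates and H = 0,
p = 1 by documented convention. The χ² reference (k−1 df) is logged as
unreliable below a total n of 8, and an exact permutation p (full
enumeration of group assignments, total n ≤ 12) is available. Dunn's
pairwise z uses the pooled-rank, tie-corrected variance with two-sided
normal p-values and no adjustment by default (adjustment optional via
Holm–Šídák); whether commercial implementations tie-correct identically is
not knowable, so the tie-corrected textbook formula is used and stated.
One-sample t-tests against 1.0 delegate to the standard implementation,
with a flagged degenerate branch for zero-variance input. Holm–Šídák is the
step-down closed form `1 − (1 − p_(j))^(m − j + 1)` with running-maximum
monotonization.

ΔΔCt follows the Livak convention: technical replicates are averaged per
(sample, gene) first; ΔCt = Ct(gene) − Ct(reference gene) per sample; ΔΔCt
subtracts the control group's mean ΔCt per gene; fold change = 2^(−ΔΔCt).
The reference gene's fold is exactly 1 and per-sample global Ct shifts
cancel — both identities are tested exactly. Per-sample ΔΔCt values are
retained for t-tests. No primer-efficiency correction or multi-reference
normalization is modelled (single reference gene, efficiency assumed 2).

## The synthetic-data generator

The generator emulates the study conditions the pipeline is designed for:

* nuclei are ellipsoids (spherical in micrometers, hence anisotropic in
  voxels) with radii 2–4 µm, placed uniformly (overlap allowed and recorded;
  an optional `min_separation` gives non-overlapping layouts for identity
  checks); real nuclei are only "small round bodies", so the ellipsoid is a
  modelling choice made for analytic ground truth;
* per-nucleus mCherry brightness is log-normal (µ = 8, σ = 0.3 in log
  space); delivered nuclei draw their true ratio from N(0.8, 0.15), others
  from N(0.05, 0.02), truncated at 0 — a two-component mixture separated by
  ≈5 sd, matching the upshift phenotype the assay scores at its default
  signal-to-noise;
* exactly `round(positive_fraction · n_nuclei)` nuclei are delivered (a
  random subset), so the realized fraction *is* the parameter and recovery
  tests measure the pipeline rather than binomial noise in the truth;
* chloroplasts are smaller ellipsoids (0.8–1.6 µm) bright in the
  autofluorescence channel, with `gfp_bleed` (default 8%) of their signal
  added into sfGFP — the artifact the exclusion mask exists to remove;
* optics and detection: anisotropic Gaussian blur (σ = (1.0, 0.8, 0.8)
  voxels), Poisson shot noise with gain 2, additive Gaussian read noise
  (sd 5), clip-and-quantize to 16 bits. `bit_depth=None` disables
  quantization; the noise-free, blur-free, unquantized mode is the regime in
  which measured ratios equal assigned truths to machine precision, and is
  what the construction-identity tests use (quantization alone introduces
  ~1e-4 relative ratio error at default brightness). Emission-band metadata
  is carried as labels only; no spectral model, diffraction PSF,
  refractive-index mismatch, cell-wall rendering or apoplast background is
  simulated.
* titrations draw the true delivered fraction from a Hill logistic
  `fmax · c^h / (c^h + EC50^h)`; each (concentration, FOV) pair uses an
  independent RNG substream keyed by the master seed, so datasets are
  reproducible piecewise. Synthetic qPCR plates shift each gene's treated
  Ct by −log2(true fold) and add Gaussian Ct noise per technical replicate.

Nucleus size, density and acquisition SNR are free parameters of the
simulator — the instrument's actual values are not published — so passing
recovery tests shows the *pipeline* is correct and calibrated under these
stated conditions, not that any particular microscope meets them. Real
acquisitions additionally contain depth-dependent attenuation, non-nuclear
mCherry structures and autofluorescent bodies outside the chloroplast
channel, none of which are modelled; the erroneous-detection failure mode
those can cause in the negative control is therefore out of the simulator's
reach.

## Problem sizes and numerics

The validation suite uses stacks of 32×256×256 to 32×384×384 voxels
(~96×128×128 to 96×192×192 µm) with 60–70 nuclei per field and 2–3 fields
per condition (≥200 nuclei per condition for fraction recovery; ~120 per
concentration across an 8-point titration) — sizes chosen so the full suite
and the acceptance script each complete in a few minutes while keeping
binomial sampling error well inside the ±5-percentage-point recovery band.
Null calibration uses 5000 control and 5000 treatment nuclei at the
record level (the calibration concerns the scoring stage, not image
rendering). All RNG use goes through `numpy` Generators seeded explicitly;
pipeline substreams are keyed `(master seed, treatment index, plant, fov)`
and derived seeds stay below 2³¹. Ratio arithmetic is float64 throughout;
measurement CSVs serialize floats at 17 significant digits and are parsed
in round-trip mode, so tables survive disk exactly.
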