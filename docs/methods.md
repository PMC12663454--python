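# Methods

This note documents the models implemented in peroxikit, the choices made
where the design was genuinely open, and what the synthetic generators do
and do not emulate.

## Hurdle count model

Per-cell organelle counts are modeled in two parts. The *zero component*
is a logistic regression for whether a cell has any detected peroxisomes,
parameterized as `P(count > 0) = logistic(x'γ)`. This sign convention —
larger coefficient means more peroxisomes — is applied consistently, so
the two components can be displayed side by side without flips. The
*positive component* is a zero-truncated negative-binomial regression with
log link: the untruncated NB has mean `μ = exp(x'β)` and variance
`μ + μ²/θ`; a single scalar dispersion θ is shared across all cells
(per-group dispersions are out of scope). The total log-likelihood
separates exactly into the binomial log-likelihood of the zero indicators
plus the truncated-NB log-likelihood of the positive counts, which the
test suite asserts identically on every fit.

Both components use the same design: intercept, treatment-coded strain
(reference WT), treatment (reference DMSO), experimental batch, and
optionally strain:treatment. Batch enters as a fixed effect: experiments
are run in batches of a few mutants plus a common WT control, and the
batch term lets all WT data be pooled across experiments without
confounding batch shifts with strain effects. Interaction columns for
strain/treatment combinations never observed are dropped before the
full-rank check; rank deficiency is an error that names the aliased
columns.

**Fitting.** The zero component is fit by iteratively reweighted least
squares with step-halving; complete separation (including the degenerate
all-positive case) is flagged rather than fatal, since separated zero
components still leave the positive component usable. The positive
component is maximized by BFGS on `(β, log θ)` with an analytic gradient,
initialized from a least-squares fit of log counts and a moment estimate
of θ; the truncation normalizer `1 − (θ/(θ+μ))^θ` is evaluated through
`log1p`/`expm1` so that the Poisson limit (θ up to 1e8) and tiny means are
stable. Standard errors come from the observed information of each
component (central-difference Hessian of the analytic gradient for the
positive part). Convergence: gradient norm below 1e-6 or the optimizer's
own relative-improvement stop.

**Inference.** A mutant's treatment response is compared to WT by
concatenating the mutant's cells (both treatments) with the *entire* WT
pool across batches, fitting the full and reduced (no interaction) models,
and referring `Λ = 2Δℓ` (clamped at zero) to a χ² with df equal to the
parameter difference — 2 per mutant with two treatments, because the
interaction enters both components. P-values across mutants are adjusted
with Benjamini–Hochberg in one family per run. Direction calls and the
heatmap use the interaction coefficients; the heatmap z-scores each
component's coefficients across strains (sample s.d.), after orienting
both components so positive means a stronger response. Dead cells are
never filtered in GLM paths; the generator's `dead_fraction` flag only
annotates rows for histogram-style summaries.

**Model families compared.** `compare_models` fits the hurdle model (this
package), a plain NB regression and a zero-inflated NB (both via
statsmodels, with the ZINB started from the hurdle solution) and reports
k, ℓ and AIC = 2k − 2ℓ. A caveat learned from simulation and reflected in
the validation scenario: when every design cell has *excess* zeros, a ZINB
can represent the hurdle truth almost exactly and the two AICs are
statistically tied. The families separate when some cells sit on the
other side — nearly all cells positive, i.e. fewer zeros than the NB for
their positive counts implies — because non-negative inflation cannot
produce a zero deficit. The model-selection scenario therefore mixes a
near-saturated condition with a heavy-zero condition, which is also what
real data look like (live treated cells almost always contain a
peroxisome; dead cells contribute zero excess).

## Mann–Whitney test

The two-sided Mann–Whitney U test used for per-figure group comparisons
supports exact enumeration (tie-free samples, all `C(n1+n2, n1)` rank
assignments, capped at 2×10⁶ combinations) and a tie-corrected normal
approximation with continuity correction. Exact mode with ties falls back
to the approximation with a warning.

## Imaging pipeline

Conventions: arrays are (z, y, x); voxel indices 0-based; the physical
position of voxel *i* at spacing *d* is `(i + 0.5)·d` µm; connectivity is
the 26-neighborhood (6 available as an option).

**LoG filter.** The Laplacian is assembled from per-axis second-derivative
Gaussian filters divided by the squared voxel spacing, so anisotropic
voxels are handled in physical units; boundaries reflect; kernels truncate
at 6σ. The response is negated (bright blobs → positive peaks) and
normalized by `σ^(2γ)` with γ = 5/4: for a 3D Gaussian blob of width σ_s
this places the maximum of the center response over filter scales exactly
at σ = σ_s (the familiar σ²-normalization would put it at √(2/3)·σ_s in
three dimensions). Since detection runs at a single scale, the
normalization affects none of the downstream decisions; it only makes the
scale-selection property exact. The default σ comes from the expected
spot radius divided by √3 (the radius of gyration of a Gaussian blob).

**Otsu threshold.** Classical 256-bin between-class-variance maximization
over the data range, using exact within-bin intensity mass, so the
partition coincides with exhaustive search whenever bins do not split
equal values (exactly true for 8-bit data). The returned threshold is the
upper edge of the optimal background bin; foreground is `value ≥
threshold`. Constant input is a degenerate-input error.

**Threshold sample.** `quantify_stack` computes the Otsu threshold over
the response values at candidate local maxima rather than over all voxels
(option `threshold_sample="voxels"` restores the whole-volume histogram).
Rationale: puncta occupy a vanishing fraction of a stack, so the
whole-volume response histogram is a single background mode whose internal
split dominates the between-class criterion; measured on a peak-SNR-5
stack, the whole-volume threshold sat inside the noise (precision 0.003)
while the maxima-sample threshold separated all true spots (recall =
precision = 1.0). The `sensitivity` setting relaxes the threshold
multiplicatively (`threshold × (1 − sensitivity)`), providing a documented
analog of the detection-sensitivity dial of punctum-counting tools.

**Seeds, watershed, size filter.** Seeds are local maxima above threshold,
greedily suppressed to a minimum physical separation (ties: higher
response, then lexicographic voxel order). Marker-based watershed (from
scikit-image) floods the negated response restricted to the thresholded
mask — a standard stand-in for tool-specific seeded watershed
constructions with the same contract: a partition of the mask among seeds.
Components smaller than `min_voxels` (default 1, i.e. keep everything) are
removed; survivors are relabeled largest-first; centroids are plain voxel
means (not intensity-weighted), volumes are voxel count × voxel volume.

**Per-cell counts and density.** Each spot is assigned to the cell label
containing its centroid voxel; spots in the background are excluded from
per-cell counts and reported separately, and every cell appears, including
zero-count cells. Numerical density is spot count divided by cytoplasmic
volume over *fully segmented* cells, interpreted as cells whose mask does
not touch the lateral (y/x) image border — axial truncation is tolerated
because the stacks are thin (~6 µm). When a nucleus mask is supplied it is
subtracted from the cell volume; without one, cell volume stands in for
cytoplasmic volume. Per-cell fluorescence uses the normalized signal
`intensity / (10,000 × cell area)`.

## Viability model

Well fluorescence is fit by ordinary least squares to genotype ×
dose × secondary-treatment (full interaction expansion) plus categorical
row, column and timepoint main effects; an optional plate term exists but
is off by default (plates are modeled jointly). Primary dose enters as a
single continuous slope — the summaries draw straight trendlines — with a
`log1p` option since doses follow a 1:2 serial dilution. The
log-likelihood is the Gaussian profile likelihood, and the three-way
interaction is tested by dropping only that term (all two-way terms
retained), df = number of dropped columns.  The likelihood-ratio statistic
is monotone in the F statistic of the same nested comparison, so the
p-value uses the exact F reference: the chi-square approximation ignores
the estimated error variance and runs about one percentage point hot at a
two-plate design's size (~960 observations, ~47 parameters), which
simulation confirmed before the switch. Spatial correction subtracts
the fitted row and column effects, each centered to mean zero, so the
plate mean is preserved and correction is idempotent. Dose–response
summaries average replicates per (genotype, secondary, dose), subtract the
dose-zero mean (every normalized curve is zero at dose 0 by construction)
and fit least-squares trendlines.

## Synthetic generators

All generators are pure functions of their parameter object, which
includes one integer seed driving a single `numpy` Generator per call.

*Counts*: one row per cell for every strain × treatment × batch condition;
the hurdle is crossed with probability `logistic(x'γ)` and positive counts
are drawn from the truncated NB by inversion. Defaults mirror the yeast
experiments: two batches, ≥100 cells per condition and batch, baseline
mean near 3 peroxisomes with most cells positive, a ~50% treatment
increase, and a mutant attenuation — magnitudes chosen to be realistic,
not fit to any particular dataset.

*Images*: non-overlapping axis-aligned ellipsoidal cells placed by
rejection sampling (identical semi-axes, so disjointness is exact via the
scaled center distance; a retry budget converts infeasible requests into
errors); spots placed uniformly inside each cell at 92% of the ellipsoid
radius with a minimum pairwise separation, again with a retry budget that
reports the achieved count on failure. The stack is background + peak-
amplitude-A anisotropic Gaussians, optionally Poisson-resampled (shot
noise) plus additive Gaussian read noise; peak SNR is defined as
`A / sqrt(A + background + σ_read²)`. The default desk-scale stack is
31×256×256 voxels at the 0.2 × 0.0509 × 0.0509 µm grid of the real
acquisitions (the full 4096² field is a parameter, not a test size). Not
emulated: real optics (the PSF is a Gaussian, not Born–Wolf), multi-channel
nuclei/actin, uneven illumination, camera gain. Passing detection tests
on these stacks therefore demonstrates the pipeline's correctness under
its own model, not robustness to every real-world artifact.

*Plates*: 16×24-well plates (two by default), conditions scattered in a
seeded randomized layout with a capacity check; fluorescence = the full
three-way linear response + additive row/column artifact vectors +
Gaussian noise, two timepoint rows per well. Defaults: ten doses from a
1:2 dilution topping at 20 (including 0), 12 replicates per condition,
noise s.d. 300 on an intercept of 10,000 — a few percent CV, typical for
resazurin-type readouts.

## Validation scenarios and problem sizes

`peroxikit.scenarios` fixes the conditions used by `tests/test_acceptance.py`
and `scripts/acceptance.py`: coefficient recovery and 95% Wald coverage at
500 cells/group over 200 replicates (recovery is assessed as bias — the
mean fitted coefficient across replicates — within ±0.1; a single
replicate's zero-component interaction has standard error ≈0.13 at these
sizes, so a per-replicate ±0.1 bound would be a coin flip rather than a
property of the estimator); LRT type-I calibration over 1000 datasets of
75 cells/group; AIC selection over 100 datasets; spot detection on a
30-spot noise-free stack and three peak-SNR-5 stacks; density recovery on
a fibroblast-like stack of true density ≈0.02 spots/µm³; viability
calibration over 1000 null plates and power over 100 plates with a
three-way effect equal to 3 noise s.d. at the top dose.

## Known limitations

- The watershed stand-in matches the contract, not the internals, of
  tool-specific Delaunay-based implementations; absolute spot volumes may
  differ from those tools even when counts agree.
- Plain voxel-mean centroids on thin stacks (2–3 z-planes per spot) carry
  up to ~1 z-voxel of error; intensity weighting is deliberately off to
  match the stated centroid definition.
- The sensitivity dial is a documented analog of external tools'
  detection-sensitivity settings, not a numerical reproduction of them.
- The exact Mann–Whitney mode refuses enumeration beyond 2×10⁶
  combinations; use the approximation for large samples.
- The hurdle optimizer assumes a fixed, shared θ; severely group-dependent
  dispersion will surface as lack of fit, not as an error.
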