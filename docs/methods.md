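# Methods

`vsdcontext` analyses mesoscopic voltage-sensitive-dye imaging (VSDI)
recordings of primary visual cortex under localized natural-movie
stimulation. Two movie patches, applied through Gaussian apertures whose
centers are separated by 2.5 FWHM, drive two distant cortical activity
spots. Eight stimulus conditions (plus two blanks) combine two movies at two
locations: four single conditions (A1, B1, A2, B2), two *coherent* pairs in
which both locations see the same movie (A1B1, A2B2) and two *incoherent*
pairs mixing the movies (A1B2, A2B1). The pipeline quantifies how the
distant ("contextual") patch modulates the local response.

## Preprocessing: evoked ΔF/F

Raw per-trial fluorescence frames are corrected in two steps, each per trial:

1. **Prestimulus normalization.** Every pixel's time series is divided by
   that pixel's mean over the prestimulus interval (200 ms at 220 Hz → 44
   samples). This removes static illumination differences across pixels.
2. **Blank correction.** The average blank signal (trials of both blank
   conditions pooled) is subtracted and the difference divided by it:
   `evoked = (stim − blank) / blank`, per pixel and per sample. Because
   heartbeat-like artifacts are phase-locked identically in stimulus and
   blank trials, this cancels them; it also cancels any multiplicative
   static gain exactly.

The corrected trials are averaged per condition. Division by the blank *at
the same sample* is the default (`blank_mode="per_sample"`); division by the
blank's temporal mean is available as `blank_mode="temporal_mean"`. Since
both corrections are affine in the stimulus frames with trial-independent
coefficients, the pipeline averages trials before applying them — exactly
equivalent to the per-trial order, but one full-size array cheaper.

Spatial profiles are means over the analysis window, 0–750 ms after
stimulus onset by default. The window origin is stimulus onset (sample index
`prestim_samples` is t = 0); `window_includes_prestim=True` re-anchors it to
trial onset for the alternative reading of an "initial 750 ms" of a trial
that includes its prestimulus interval.

## Dual-Gaussian spatial model

Each condition's profile is modelled as the superposition of two rotated 2D
Gaussians, one per spot:

    G(x, y) = A exp(−[(x−μx)²/(2σx²) + (y−μy)²/(2σy²) + ρ(x−μx)(y−μy)])

with x the medio-lateral (column) and y the antero-posterior (row) pixel
coordinate; σ are standard deviations (FWHM = 2√(2 ln 2) σ ≈ 2.355 σ). All
12 parameters are estimated simultaneously by bounded
trust-region-reflective least squares (`scipy.optimize.least_squares`,
max 2000 function evaluations, tolerances 1e-12).

Numerical choices:

* **Decay constraint.** The exponent's quadratic form is positive definite
  iff |ρ| < 1/(σx σy). The optimiser works on q = ρ σx σy with
  |q| ≤ 1 − 1e-3, which enforces the bound for every σ it visits and keeps
  the fitted surface decaying.
* **Center boxes.** Each Gaussian's center is constrained within
  `center_box` (default 5 px) of the known peak-response location of its
  spot. This is what makes the *indirect* amplitude at the non-stimulated
  spot estimable in single conditions: two Gaussians are fitted for every
  condition, including single ones.
* **Bounds.** σ ∈ [1 px, max(ys, xs)/2]; A symmetric at ±2·max|profile|, so
  indirect suppression (negative A) is representable.
* **Initialization and multi-start.** Initial values come from the windowed
  local maximum around each approximate center plus second moments of its
  above-half-max neighbourhood (ρ₀ = 0). Because that heuristic always
  seeds a below-noise-floor spot on a *positive* noise bump, extra starts
  seeded from the windowed trough are also run and the lowest-cost solution
  kept; this makes local-optimum selection sign-symmetric and the mean
  indirect amplitude unbiased under the null.
* **Degenerate input.** Coincident approximate centers are rejected (the
  analysis presumes well-separated spots); a flat profile initializes with
  a small positive amplitude and a warning; non-convergence is flagged on
  the result, never raised.

Fit quality is the Pearson correlation between the fitted surface and the
data over all pixels.

## Contextual metrics

For each (location, movie) comparison cell — 4 per experiment — four
characteristic fits are collected: *direct* (own patch alone), *indirect*
(distant patch alone), *coherent* and *incoherent* (the pair conditions
containing the cell's patch). Amplitude metrics per cell, in percent of the
direct peak A_dir:

* total facilitation = 100 (A_coh − A_dir) / A_dir
* superadditive = 100 (A_coh − (A_dir + A_ind)) / A_dir
* linear = total − superadditive = 100 A_ind / A_dir
* specificity = 100 (A_coh − A_incoh) / A_incoh
* incoherent vs direct = 100 (A_incoh − A_dir) / A_dir

Percentages are computed per cell first and then averaged, so the paired
tests (Wilcoxon sign-rank, sign test, paired t) act on the same per-cell
values as the point estimate. Cells whose direct fit failed to converge or
has A_dir ≤ 0 are dropped pairwise and counted. The *joint spread* of a fit
is the geometric mean √(σx σy) (an arithmetic-mean variant is provided);
spread metrics report percent changes of σx, σy and the joint spread for the
coherent-vs-direct and coherent-vs-incoherent contrasts.

Confidence intervals are percentile bootstrap (1000 repetitions, α = 0.05 by
default), seeded. The percentile variant is the simplest choice consistent
with the procedure; its interval for a mean is mildly anti-conservative at
small n (coverage ≈ 0.93 at n = 30, ≈ 0.94–0.95 at n = 100 — the sample size
used in the calibration tests). The sign-rank test uses the exact null
distribution for n ≤ 25 without ties and the continuity-corrected normal
approximation otherwise; the sign test is exact binomial arithmetic. No
multiple-testing correction is applied across time bins.

## Time-course analysis

Regions of interest are the pixels within the highest 5th percentile of each
single-condition profile (threshold by lower-interpolation percentile,
boundary value *included*; the convention is tested against a sort-based
oracle). Contested pixels go to the location with the larger value, and pair
conditions always reuse the masks defined from the single (no-context)
conditions. ROI-mean traces are resampled from the 220 Hz acquisition rate
to the 200 Hz analysis rate by linear interpolation (amplitude loss < 1 %
for content below ~10 Hz, no edge transients). Per activation type the
across-cell median trace is reported with a per-bin sign-rank test against
zero; coherent−direct and coherent−incoherent differences are formed per
cell before aggregation. Cross-location Pearson correlations over the
stimulus window define r_single (A-alone vs B-alone, same movie),
r_coherent and r_incoherent (both locations within one pair condition).

**ROI selection effect.** Because the masks are chosen as the top pixels of
a *noisy* single-condition profile, that condition's own ROI trace is
slightly noise-inflated relative to other conditions read through the same
mask; difference traces against it inherit a small negative offset. This is
inherent to percentile-ROI analyses and negligible when evoked amplitudes
dominate the profile noise, but it matters when calibrating the per-bin test
under a no-effect generator: the calibration therefore uses masks derived
from the true (noise-free) spot profiles, isolating the size of the test
itself.

## Synthetic-data generator

The generator produces raw trial stacks with the statistical structure the
analysis assumes, with exported ground truth:

    frames = gain_field(x, y) · [1 + evoked(x, y, t) + heartbeat(t) + ε]

* **Gain field**: 1 + a smooth zero-mean random field (amplitude 0.2),
  emulating illumination inhomogeneity; cancelled exactly by preprocessing.
* **Drives**: each (movie, location) has a temporal drive — low-pass-filtered
  (4th-order Butterworth, 25 Hz) Gaussian noise, zero during prestim,
  standardized and offset by 1.5 during the stimulus so evoked activity is
  net positive. Same-movie drives at the two locations mix a shared
  component with weight √c, giving expected correlation c = `drive_coh`
  (default 0.6); different movies are independent.
* **Evoked term**: per stimulated spot, amp · G_spot(x, y) · drive(t) with
  A-peak amp_direct = 2.3e-4 (the scale of reported direct peaks). Single
  conditions add an indirect copy `amp_indirect_frac` (default 0.03) of the
  presented patch's drive at the distant spot. Paired conditions multiply
  both spots by `facilitation_gain_coh` = 1.45 or
  `facilitation_gain_incoh` = 1.2 and mix each site's drive convexly with a
  fraction `pair_coupling_frac` = 0.15 of the distant patch's drive — the
  lateral-interaction mechanism that raises r_coherent above r_single.
  Convex mixing leaves expected amplitudes unchanged, so the implied
  facilitation percentages are exactly 100·(gain − 1). Coherent (incoherent)
  pairs also widen σy by 18 % (8.5 %), emulating spread growth along the
  direction of the context; σx is untouched.
* **Heartbeat**: a sinusoid (2.5 Hz, amplitude 0.01) phase-locked
  identically across all trials and conditions including blanks — the
  property that makes blank subtraction exact.
* **Noise**: i.i.d. Gaussian per pixel/sample/trial, sd 6.5e-4 of the
  baseline fluorescence. This value was derived analytically so that, after
  trial and window averaging (including the static noise floor contributed
  by prestimulus normalization, which time-averaging does not reduce), the
  model-vs-data fit correlation across conditions lands in the high-0.8
  range characteristic of good VSDI recordings.

All randomness derives from a single seed through keyed `SeedSequence`
streams, so a given (movie, location) drive is bit-identical across
conditions and whole experiments are exactly reproducible.

Geometry defaults: 90 × 190 px at 0.05 mm/px (a ~10 × 5 mm field of view),
spot σ = 6 px, centers separated along the antero-posterior (row) axis by
2.5 FWHM. `SyntheticConfig.small()` is the scaled-down 32 × 64 grid
(σ = 2.5 px, 800 ms stimulus) used throughout the tests and the acceptance
script; replicated Monte-Carlo studies use a further-reduced 24 × 48 grid
with 6 trials. These sizes keep simulation studies cheap while preserving
every structural property the analysis relies on.

### What the generator does and does not emulate

It reproduces the features the analysis is sensitive to: two Gaussian spots,
blank-shared artifacts, multiplicative gain, correlated band-limited drives,
paired-condition facilitation, anisotropic spread growth and trial noise. It
does **not** model photon statistics, dye bleaching, vascular artifacts,
orientation-map structure, spatially correlated noise, or genuine
natural-movie statistics (drives are filtered noise; in particular,
*different* movies are exactly independent, whereas real movie pairs retain
residual low-level correlations — which is why the generator's r_incoherent
sits near the coupling-induced floor rather than near r_single as observed
in real data). Passing recovery tests therefore demonstrate correctness of
the analysis under its own assumptions, not robustness to everything real
recordings contain.

## Deposited-data I/O

Deposited experiments are MAT files holding a struct with fields `d`
([space, time, condition]), `ys` and `xs`. The space axis is the
column-major flattening of a ys × xs image (i_space = row + ys·col), and the
ten conditions follow the documented 1-based order (blanks, A1B1, A1, B1,
A2B2, A2, B2, A1B2, A2B1), translated to 0-based labels at the I/O boundary.
Both blank conditions are stored; downstream code uses their pooled mean.
Frame rate and prestimulus length are not stored in the files and default to
220 Hz and 200 ms. Evoked data loaded this way are treated as already
preprocessed; the ΔF/F steps apply to raw trial stacks only.

## Known limitations

* The indirect amplitude sits at or below the profile noise floor under the
  default conditions (as in the motivating experiments, where it was not
  statistically significant); its per-cell estimates are noisy, and the
  linear component inherits that variance.
* Percentile-bootstrap CIs undercover by a few points for n ≲ 30 cells.
* The exact printed form of the Gaussian equation in the source literature
  is typographically corrupted; the standard rotated-Gaussian form above is
  the unique interpretation consistent with the parameter descriptions, and
  is the only form implemented.
* ROI percentiles are taken over all pixels of the profile; restricting to a
  bounding box around the active region is available via the percentile
  threshold helper but is not the default.
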