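# Methods

## Scope and model

`sptquant` measures chromatin binding of a nuclear protein two ways: by
classifying single-molecule trajectories into bound and mobile populations
through their apparent diffusion coefficients, and by scoring accumulation
at laser-microirradiation stripes as a background-corrected brightness
ratio. Both analyses are validated end to end against a synthetic-data
generator whose ground truth is known exactly.

### Motion model

Molecules perform 2-D Brownian motion inside a nuclear mask. A molecule is
bound with probability `f_bound` and keeps its state for the whole
recording; per-axis per-frame displacements are `N(0, 2·D·Δt)` with
`D = d_bound` (default 0.02 µm²/s) or `d_mobile` (default 0.5 µm²/s, the
mode of the mobile population in the experiments this models). Defaults for
geometry follow the target acquisition: 256×256 px at 0.096 µm/px, 20 ms
frames, up to 4,000 frames.

A proposed step that exits the mask is *reflected by reversal*: the
molecule moves to `x − δ` instead of `x + δ` (and stays put in the rare
case that also exits). Reversal preserves the step length exactly, so the
lag-1 MSD — the only displacement statistic the analysis consumes — is
unaffected by boundary handling, while molecule number stays constant as in
a closed nucleus. This is deliberately simpler than specular reflection off
a rasterized boundary, whose normal direction is ill-defined at pixel
corners.

Photoblinking is a two-state Markov chain per frame (`k_off_frame`,
`k_on_frame`), started from its stationary distribution
`p_on = k_on/(k_on+k_off)`. Photobleaching is not modeled. Photon yield,
background and blink rates are not published for the dye/illumination this
emulates; the defaults (1,000 photons per spot per frame, 10 background
photons/px, k_off = 0.12, k_on = 0.05) are realistic for a bright rhodamine
dye under HILO illumination and are assumptions, not fitted values.

### Imaging model

Each emitting molecule contributes an isotropic Gaussian PSF (sd
`psf_sigma`, default 1 px) integrated exactly over each pixel via
error-function differences — not sampled at pixel centers — so that
sub-pixel localization tests are meaningful. Expected spot photons plus a
uniform background expectation are Poisson-sampled per pixel; per-pixel
sampling of the summed expectation is distributionally identical to drawing
each spot's photon count and thinning it over pixels. Counts are written as
16-bit grayscale TIFF. No EM-gain, read-noise or motion-blur model is
included.

Ground truth is emitted in µm in a frame whose origin is the top-left pixel
*corner* (pixel (0,0) spans [0,1)×[0,1) px; x = column axis). Detection
reports 0-based pixel-*center* coordinates, which sit exactly 0.5 px below
that frame; the constant offset cancels in every displacement and is
accounted for where tests compare positions directly.

### Detection and localization

Frames are band-passed with a difference of Gaussians (σ = 1 and 3 px by
default, bracketing the PSF), thresholded at mean + `k`·SD of the filtered
frame (`k` = 5), and 8-neighborhood local maxima are kept, suppressing any
maximum within one ROI side (7 px) of a stronger one. Candidates whose
7×7 ROI would leave the image are dropped and logged. Each ROI is localized
by the phasor method: the phase of the first-harmonic DFT coefficient along
each axis, wrapped to (−K/2, K/2]. The raw ROI is used without apodization;
a constant background contributes exactly zero to the first harmonic, so no
background subtraction is needed for the position. On noiseless
pixel-integrated spots the phasor estimate agrees with a nonlinear
least-squares Gaussian fit to ~1×10⁻⁴ px; the filter scales, threshold and
ROI size are package defaults (the original acquisition software's internal
settings are not published) and are configurable.

### Linking

Localizations link to open tracks when within 8 px (Euclidean, inclusive;
distances in pixels). Per frame, the gate-respecting one-to-one assignment
minimizing total squared displacement is solved with the Hungarian
algorithm; leaving a track or localization unmatched costs the squared
radius, so linking is always preferred within the gate. Greedy
nearest-neighbor linking is order-dependent and was rejected; an exhaustive
enumeration oracle in the test suite pins the semantics. A track missed in
one frame stays open for one more frame (memory 1) and may reconnect within
the *same* 8 px radius measured from its last seen position — the radius is
not inflated for gap closure, a conservative choice where the original
behavior is unstated. Tracks with fewer than 4 steps (5 localizations) are
discarded.

### Diffusion estimation and classification

`MSD` is the lag-1 mean squared displacement over consecutive-frame steps
only; steps across a bridged gap are excluded rather than divided by 2Δt
(excluding them is unbiased; the choice is configurable at the data level
since gap flags are stored per localization). `D = MSD/(4·Δt)` with
Δt = 0.020 s. A track is bound iff `D ≤ 0.3 µm²/s` — the threshold is
inclusive on the bound side. Bound fractions are computed per cell, then
compared across conditions with a one-way fixed-effects ANOVA on the
per-cell values (pooling tracks across cells would hide cell-to-cell
variance). Histograms of `D` default to 0.05 µm²/s bins on [0, 2] with an
overflow bin.

Calibration facts used by the tests: for a track of `n` independent
single-frame steps with per-axis localization error σ,
`E[D] = D_true + σ²/Δt` and `D·2n/(D_true + σ²/Δt) ~ χ²_{2n}`. The
closed-form mixture of the two populations' chi-square tail probabilities
(`expected_bound_fraction`) predicts the *measured* bound fraction
including threshold misclassification; at 10,000 simulated tracks the
empirical fraction matches it to well within Monte-Carlo error. With
per-position (rather than per-step) noise, consecutive steps are weakly
negatively correlated; the correlation of *squared* steps is the square of
that and is negligible at the σ used, so the chi-square form remains an
accurate description.

### Stripe recruitment

The stripe region mean rises as
`baseline + amplitude·(1 − e^{−rate·t_post})` after a configurable number
of pre-irradiation timepoints (`t_post` = 1 at the first post-irradiation
frame); the nucleus remainder and background stay flat; pixel noise is
additive Gaussian. A saturating single exponential is the simplest form
matching observed recruitment curves, which are reported without a fitted
model. The analysis computes region means (masks may vary per timepoint to
follow a migrating cell), `Sx = (Ax − B)/(Cx − B)` (requiring `Cx > B`),
and the first-timepoint normalization: subtract `raw[0] − 1` from every
timepoint. Normalization is applied **per cell** before averaging, so cells
from different fields remain comparable; an averaged-first variant can be
obtained by aggregating raw curves and normalizing the mean. SEM uses the
n−1 sample SD divided by √n; a single-cell condition reports SEM 0 with a
warning. `Sx` is exactly invariant under affine rescaling of the image.

## Problem sizes and what the tests show

The validation suite runs entirely on synthetic data at sizes chosen to
keep Monte-Carlo error small while remaining desk-scale: estimator
calibration and mixture recovery use 10,000 ground-truth tracks; the
end-to-end contrast uses the real per-condition design (3 cells per
condition) with 600-frame, 128-px movies of 150 blinking molecules,
yielding >1,000 kept tracks per cell; stripe recovery uses 5 cells per
condition, matching the experimental design it emulates.

Passing tests demonstrate that the *pipeline* recovers what the *generator*
put in. Real recordings differ in ways the generator deliberately omits:
non-uniform nuclear background and bright foci, defocus and axial loss of
fast molecules, motion blur within the 20 ms exposure, camera EM-gain
statistics, drift, and density heterogeneity. Two consequences seen even in
simulation are worth noting: localization error inflates every `D` by
σ²/Δt, and at realistic spot densities occasional wrong links inflate the
`D` of some genuinely bound tracks, biasing recovered bound fractions
below the molecular truth. The between-condition *contrast* is robust to
both effects, which is why the condition comparison — not the absolute
fraction — is the endpoint.

## Numerical and interface choices

- One integer seed drives everything; per-stage and per-cell generators are
  derived via `SeedSequence` so runs are bit-reproducible (the acceptance
  script verifies this by hashing artifacts).
- Assignment ties in linking are resolved by the Hungarian solver's
  deterministic order; ties have measure zero for continuous positions.
- Degenerate ANOVA input (all values identical) returns F = 0, p = 1; a
  zero within-group variance with distinct groups returns F = ∞, p = 0.
- Physical metadata (pixel size, frame interval) travels in configs, never
  in TIFF tags. CSVs are UTF-8, comma-separated, floats at 9 significant
  digits. Unknown config keys are rejected.
- Edge candidates (ROI crossing the image border) are dropped, not padded;
  an all-zero ROI raises rather than returning a fabricated position.

## Known limitations

No Kalman/motion-model linking, no merge/split handling, no multi-lag MSD
fitting or hidden-Markov segmentation within tracks, no 3-D or astigmatic
PSFs, no photobleaching or drift correction, no automated stripe/nucleus
segmentation. The bound/mobile threshold is a fixed boundary, not a fitted
mixture split.
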