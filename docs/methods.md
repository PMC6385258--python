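# Methods

This note documents the models implemented in `qdc3dm`, the parameters
that matter, the numerical choices behind them, and what the synthetic
test data does and does not establish about real microscopy data.

## Counting by blinking quantization

A diffraction-limited spot containing k independently blinking quantum
dots produces a 3×3-pixel summed intensity trace whose histogram shows
k + 1 levels (0…k emitters simultaneously on). The trace histogram
(100 bins over the trace range) is fit by unweighted least squares to a
mixture of one symmetric Gaussian — the off-state/background level — plus
1–4 additional components; the component count minimizing
AIC = n_bin·ln(RSS/n_bin) + 2(3·n_Gauss − 1) among fits passing the
quality criteria determines k = n_Gauss − 1.

**Component family.** The 2–5-component sweep uses symmetric Gaussians.
The skew-normal signal component (location/scale/shape) is reserved for
the dedicated two-function single-QD identification fit. Giving skew
freedom to the sweep lets the optimizer split one intensity level into a
mirrored pair of half-Gaussians that satisfies every distinctness
criterion while being pure over-fitting; we observed ~25% over-counting
in that configuration.

**Fit quality criteria.** A fit is accepted only if (1) the Pearson
correlation between fit and histogram is ≥ 0.98; (2) every component
carries ≥ 8% of the total fitted mass; (3) the overlap coefficient
∫min(f_i, f_j) of any two unit-normalized component densities is ≤ 0.75;
(4) each component's fitted mass differs ≤ 20% from the histogram mass in
the bins where that component has maximum responsibility. Criteria (3)
and (4) are stated qualitatively in the literature this method derives
from; the overlap coefficient and the maximum-responsibility region are
this package's concrete definitions.

**Level resolvability.** In addition to the four criteria, any two
components must have means separated by at least the sum of their
standard deviations. Without this, two symmetric components ~1.6σ apart
can split one level, pass the overlap criterion (OVL ≈ 0.42), and win the
AIC comparison — because the unweighted RSS is dominated by high-count
bins whose Poisson variance dwarfs the AIC penalty of 6 per extra
component. The separation rule generalizes the single-QD acceptance
condition (signal and background separated by ≥ σ₁ + σ₂) to all component
pairs and acts as this package's surrogate for single-emitter
photophysics criteria that the source literature references but does not
reproduce.

**Bin integration.** Model bin counts are component masses times the
within-bin density integral, computed with 3-point Gauss–Legendre
quadrature per bin. With bright emitters a level can be only ~2 bins wide
(σ ≈ 1.7 bin widths); evaluating the density at bin centers decouples the
mass parameters from the counts they explain and silently breaks
criterion (4) on perfectly good fits.

**Optimization.** Multi-start trust-region least squares (8 starts,
seeded; quantile-spaced location initializations with jitter), analytic
Jacobian, bounds keeping scales positive and skews in [−10, 10]. The
best-RSS converged start is kept; total failure returns a `fit-failed`
status rather than raising. Ties in AIC resolve to fewer components.

**Single-QD classification.** A spot is accepted as a single QD when the
two-component fit (Gaussian noise + skew-normal signal) passes all
criteria, the three-component fit does not beat it under AIC while itself
passing, and the two levels are separated by ≥ σ₁ + σ₂. The stringency is
deliberately asymmetric: excluding a true single costs calibration
statistics; admitting a doublet corrupts the calibration mean.

## Deconvolution

Plain multiplicative Richardson–Lucy with a fixed PSF, default 60
iterations, reflective boundaries (FFT convolution on a reflect-padded
volume), non-negativity preserved by construction. No regularization by
default; a Tikhonov-style damping exponent is available for noisy data.
Flux is conserved to <1% for interior sources, and after 60 iterations
essentially all of a point source's flux falls inside the 3×3×11 voxel
integration window, which is what makes window intensities quantized in
the emitter number. The PSF may be measured from bead stacks
(`psf_from_beads`: background-subtracted, aligned, averaged, normalized)
or generated as a separable Gaussian.

The diffuse background level (stack median) is subtracted before
deconvolution. Richardson–Lucy models point-like emission; iterating on
an image with a uniform pedestal siphons background photons into bright
blobs, adding a near-constant offset to every spot's integrated
intensity. The offset cancels when counting single-QD spots but biases
multi-emitter counts low, so it is removed at the source.

## Spot detection

*2D (movies):* matched-filter peak test against locally flat background
(zero-sum Gaussian template; per-pixel false-alarm rate default 10⁻⁶ under
the frame's MAD-estimated noise), sub-pixel least-squares Gaussian fit,
subtract-and-repeat deflation. When the one-peak fit leaves a decisive
lack of fit, a two-peak hypothesis is tested in the same window and
accepted if it halves the residual with both peaks detectable and ≥ 1 px
apart; matched-filter responses of ~2 px pairs are unimodal, so without
this the deflation loop reports a spurious midpoint spot.

*3D (deconvolved stacks):* thresholding at median + k·1.4826·MAD
(default k = 6) on a 3×3×3 box-smoothed copy of the stack — deconvolution
of low backgrounds leaves heavy-tailed single-voxel speckle that the
smoothing suppresses — followed by 26-connected component labeling.
Components whose centroids fall within 2 px laterally and 6 planes
axially are merged before the minimum-size filter, because a QD that
blinks during the z-scan fragments into several clumps stacked in z.
Each spot's intensity is the integrated, median-subtracted flux over its
1-voxel-dilated support: identical to the 3×3×11 window for a compact
single emitter, but correct for extended multi-emitter components
(clusters, endosome-scale accumulations) that overflow any fixed window.
Detections are confirmed on the raw stack (3×3×11 excess > 3 sd of
background window sums) to reject deconvolution-amplified noise blobs.

Rounding is half-up; indices are 0-based internally and 1-based in
exported tables. Spots whose integration window would clip the stack
border (1 px laterally, 5 planes axially) are flagged and excluded from
calibration and counting.

## Membrane geometry and internalization

The membrane surface is the boundary of the 3D alpha complex of the
stain point cloud: Delaunay tetrahedralization, keep tetrahedra with
circumradius ≤ α (default 50), boundary triangles are faces of exactly
one kept tetrahedron. Coordinates are made isotropic before
tetrahedralization by scaling z with z_spacing/pixel_size, so α is a
length in xy-pixel units. For each ligand spot a ray from the nucleus
centroid through the spot is intersected with the boundary triangles
(Möller–Trumbore); the **outermost** crossing defines the surface point —
the conservative choice for concave cells, producing fewer false
"internalized" labels — and ρ = |spot − nucleus| / |surface − nucleus|.
Spots with ρ ≤ 0.8 are internalized; the internalized fraction weights
each spot by its calibrated QD count. Rays that exit an open surface
without crossing mark the spot unresolved (NaN) and drop it from the
fraction.

Pattern-registered projections rigidly align each adhesion-pattern mask
to a reference by centroid and principal axes, resolving the 180°
ambiguity by maximizing mask overlap; cells with aligned overlap < 80%
are excluded with a warning.

## Binding simulator

Free receptor R, surface complex B and internalized complex C per cell
obey R′ = −κR + k_off·B, B′ = κR − (k_off + k_int)B, C′ = k_int·B with
κ = k_on·[EGF]₀ (constant ligand: the extracellular reservoir,
~16.7 nL/cell, dwarfs the ~1.7 pL cell volume). Working in receptor copy
numbers sidesteps any ambiguity about which conversion volume applies —
the formulation is exact for constant ligand. The solution is closed
form: B(t) = κN_R(e^{λ₁t} − e^{λ₂t})/(λ₁ − λ₂) with λ₁,₂ the roots of
s² + (κ + k_off + k_int)s + κ·k_int, and C(t) by integration; the
critically damped case is handled by its limit. Rate presets:

| preset | k_on (M⁻¹s⁻¹) | k_off (s⁻¹) | k_int (s⁻¹) |
|--------|---------------|-------------|-------------|
| 37C    | 1.03×10⁶      | 5.67×10⁻³   | 5.00×10⁻⁴   |
| 4C     | 1.03×10⁴      | 2.84×10⁻⁴   | 0           |

The 4 °C values approximate association 100× and dissociation 20× slower
than at 37 °C, with internalization arrested on ice.

Receptor copy numbers are Gamma(a, b) with shape a = 3.34 (inverse
expression noise) and mean a·b = 100,000 active receptors per cell. The
population bound-ligand distribution is the gamma-weighted Poisson
mixture: the gamma is discretized on a 2000-node midpoint-quantile grid
(renormalized; places nodes where the mass is), each node's kinetic mean
is spread by a Poisson, and the support is truncated at
mean + 12·√mean with an error raised if > 10⁻⁴ of mass is lost.
`sample_cells` draws finite populations from the same model. The
flow-cytometry isotherm utilities compute percent-of-maximum binding and
fit the Langmuir form P(c) = B_max·c/(K_D + c) by nonlinear least
squares, warning when the sampled concentrations do not bracket K_D.

## Synthetic microscope

Emitters are rendered under a separable pixel-integrated Gaussian PSF
(σ_xy = 1.0 px at 160 nm pixels, σ_z = 1.2 planes at 250 nm spacing —
a 100×/1.45 NA EMCCD geometry), so brightness is conserved exactly on an
unbounded grid. Noise is Poisson shot noise on quantum-efficiency-scaled
expected photons followed by Gaussian read noise (σ = 3 counts), applied
per frame/plane; read noise can push pixels slightly negative, which the
pipeline clips before deconvolution. All randomness descends from one
seed; identical (configuration, seed) reproduces output bit for bit.

Blinking is a two-state Markov chain per frame with switch probabilities
0.5/0.5 per 100 ms frame: stationary on-fraction 0.5 (so every mixture
level is well populated for quantization) and mean dwell ~2 frames. The
dwell choice matters for 3D stacks: blinking is applied per plane, and a
QD dark across all planes near its focus is invisible to any
intensity-based counter. With ~2-frame dwells ~2–3% of QDs are lost this
way; at ~3.3-frame dwells the loss reaches 12–14% and caps end-to-end
recovery near 0.87 regardless of detector quality. Real QD blinking is
power-law over ms–s; the two-state chain with exposure-scale dwells is
the regime in which per-spot counting is designed to operate, and slower
blinking reproduces the known undercounting failure mode rather than a
bug. Default emitter brightness is 5000 detected photons per 100 ms
frame (5×10⁴ s⁻¹, conservative for bright stable QDs); the diffuse
cellular background defaults to 3 photons/px/frame in the counting
channel, reflecting the choice of a near-infrared emission band precisely
because cellular autofluorescence is negligible there. Stronger
backgrounds are exercised explicitly in the autofluorescence and AUROC
analyses.

The cell fixture places the membrane stain on an ellipsoid fitted to the
adhesion-pattern rectangle (1% radial jitter), draws the bound-ligand
count from the kinetic model (or takes a fixed count), and places each
ligand internal (ρ uniform in 0.1–0.75) or on the surface according to
the requested internalized fraction, recording per-spot truth labels.

**What the generator does not emulate:** power-law blinking statistics,
photobleaching chemistry (only a qualitative exponential flag), realistic
organelle morphology, spectral crosstalk, depth-dependent PSF
aberrations, and stage drift. Tests passing on this generator establish
the correctness of the calibration arithmetic, model selection, geometry
and kinetics under controlled optics — not performance on aberrated,
drifting, or power-law-blinking real data.

## Problem sizes in the test suite

The validation suite uses 96–150 px fields with 40 z-planes, 600-frame
movies for in-scene calibration, 4000-frame traces for quantization
statistics, 9 synthetic cells (3 × {10, 100, 1000} ligands) for count
linearity, 500-point membranes with 500 test spots for geometry, and a
2000-node quadrature for the binding mixture. These sizes give each
statistical assertion comfortable margins (e.g. ≥ 3 standard errors)
while keeping the full suite in the minutes range on one CPU.

## Known limitations

- Counting accuracy degrades gracefully but irrecoverably when blinking
  off-dwells become long relative to the focal transit of the z-scan
  (dark-QD loss); the package measures what is detectable.
- End-to-end totals recover ~93–100% of ground truth on the synthetic
  suite. The residual deficit is a characterized small bias: compact
  calibration spots pick up a few percent of residual background speckle
  that extended multi-emitter components dilute, and calibration singles
  are mildly detection-conditioned toward brighter blinking
  realizations.
- The deconvolution stand-in is plain Richardson–Lucy; equivalence with
  proprietary commercial restoration cannot be verified, and acceptance
  rests on flux-conservation and quantization-restoration invariants.
- The binding model ignores ligand depletion, receptor oligomerization,
  spatial membrane microdomains and autocrine ligand production.
- Trajectory linking across frames (tracking), drift correction and
  nucleus segmentation are out of scope; nucleus centroids are inputs.
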