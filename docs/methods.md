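# Methods

This note documents the models implemented in `adhesiontfm`, the
parameter choices that matter, what the synthetic scenes do and do not
emulate, and the numerical decisions taken where the underlying methods
literature leaves the design open.

## Point-source detection

Nascent adhesions and fiducial beads are diffraction-limited, so frames
are filtered with a scale-normalized Laplacian of Gaussian (negated:
bright blobs → positive peaks). The frame mean is subtracted first, which
cancels the DC leakage of the truncated discrete kernel and makes the
response to a constant image exactly zero.

**Threshold.** The detection threshold is noise-derived: median of the
LoG response plus its MAD-based robust sd scaled by the normal quantile at
1 − α/N (N = pixels per frame, α = 0.05 by default). This Bonferroni-style
control bounds the probability of any false maximum per frame by roughly
α, which is testable under the null and leaves recall untouched at
realistic SNR.

**Localization.** Each surviving 8-connected local maximum (ties broken
in raster order) is fit with A·exp(−((x−x₀)² + (y−y₀)²)/2σ²) + b over a
±4σ window, with σ held fixed at 2.1 px (~180 nm at the default
0.086 μm/px). Holding σ fixed is the standard choice when the PSF is
known: it removes one degree of freedom and stabilizes amplitude
estimates at low SNR. Localization precision reaches within 1.5× of the
Cramér–Rao bound in the test suite's Monte-Carlo.

**Goodness of fit.** Detections are filtered by asking whether the fit
residuals look like pure noise: a Kolmogorov–Smirnov test of the
self-standardized residuals against N(0, 1), rejecting at p < 0.05. A
variance-based chi-square test against a global noise estimate was
considered and rejected: with ~360 residual pixels it necessarily
discards ≥ 5% of genuine point sources when perfectly calibrated and far
more when the frame-level noise estimate is off by even 1–2%. The shape
test is conservative for true spots (location and scale are estimated
from the same residuals) yet rejects extended, non-Gaussian structures
essentially always — exactly the discrimination the filter exists for.
Measured on synthetic frames: ~0.2% true-spot loss, 100% rejection of
matched-brightness square blobs.

## FC/FA segmentation and classification

Paxillin frames are smoothed (Gaussian, σ = 1 px) and
background-subtracted with a morphological opening (disk, radius 15 px —
above FA scale). The opening-based background passes smooth illumination
gradients through unchanged, leaves adhesion-scale structures out of the
background estimate, and makes the operator nearly idempotent.

The foreground threshold blends Otsu's bimodal criterion with Rosin's
unimodal triangle rule (maximum distance from the histogram-peak-to-tail
chord). The default combination is their arithmetic mean — a bimodal and
a unimodal estimator bracket the practical cases, and the mean behaves
sensibly on both; `otsu`, `rosin`, `min` and `max` modes are selectable,
and both component values are logged per frame.

Components (8-connected) are classified by physical area with intervals
closed on the left: ≤ 0.2 μm² discarded, (0.2, 0.24) μm² retained but
below the focal-complex floor (`below_FC` — still a legitimate NA
footprint), [0.24, 0.6) μm² FC, ≥ 0.6 μm² FA. Shape is summarized by
the second-moment ellipse; the eccentricity measure is the minor/major
axis ratio (1 = circular).

## Tracking and status

Linking is frame-to-frame global linear assignment (Hungarian algorithm)
with cost = squared displacement, gated at a search radius (default 3 px)
and with birth/death alternatives priced at radius². A second assignment
pass closes gaps of up to `max_gap` (default 2) missing frames, with the
gate scaled by the gap length. Every detection belongs to exactly one
track; singletons are length-1 tracks, so track lengths sum to the
detection count by construction.

Status per frame: a tracked point inside an FA-class region is `FA`,
inside FC-class `FC`, otherwise `NA`; frames before the first detection
are `BA` on the movie timeline. Lifetime is (frames spanned) × Δt; tracks
alive in the first or last movie frame are censored and excluded from
lifetime summaries. The nucleating fraction counts tracks first detected
after frame 0 that persist ≥ 3 frames, over all NA-containing tracks; the
maturing fraction counts matured tracks over NA-born tracks. Both
definitions are operational choices (reported as such in outputs) since
"nucleating NA" admits several readings.

## Assembly / disassembly kinetics

Intensity traces are modeled as exponential in their growth and decay
phases: the assembly rate constant is the slope of ln(I/I₀) versus time
with I₀ fixed at the first sample and candidate windows extending from
the start to each index up to the intensity peak; disassembly mirrors
this from the peak to the end, with I₀ at each candidate window's start.
Ordinary least squares per window; the window with the largest adjusted
R² (= 1 − (1−R²)(n−1)/(n−2)) wins, ties going to the longer window.
Natural log; rates reported per minute (slope per second × 60, exact).

**Minimum window: 10 samples** (3.3 min at the 20 s frame interval).
This is the one genuinely coupled choice in the module: maximizing
adjusted R² over many short candidate windows inflates the best R² on
trend-free noise, and with 4-point windows the 0.3 adjusted-R² filter
retains ~49% of pure-noise traces — i.e. it stops filtering anything.
At 10 samples the null retention drops to ~12% while the window search
still localizes a planted growth/plateau changepoint to ±1 sample in
≈ 85–90% of trials at 5% multiplicative noise and recovers rate constants
to ~1% (median) at 10% noise. The window length is exposed as
`min_window` for traces sampled differently.

Windows containing non-positive background-subtracted intensities are
skipped (the trace survives; only those windows are invalid). A trace
whose best adjusted R² falls below 0.3 is flagged noise-like and dropped
by `filter_by_adjusted_r2`.

## Traction force microscopy

**Forward model.** The substrate is a linear-elastic half-space with
Young's modulus 5000 Pa and Poisson ratio 0.5 (incompressible silicone;
ν is configurable). Tangential surface traction produces surface
displacement through the Boussinesq–Cerruti Green's tensor

    G_ij(r) = (1 + ν)/(π E r) [(1 − ν) δ_ij + ν r_i r_j / r²].

Traction is piecewise constant on a regular square mesh, and G is
integrated **analytically** over each rectangular element (the kernel
integrals ∬1/r, ∬x²/r³, ∬xy/r³ all have closed forms evaluated at the
element corners, verified against adaptive quadrature in the tests).
The element integrals remain finite for evaluation points inside the
element, so the forward operator never touches the kernel singularity.
This direct dense assembly is the minimal faithful counterpart of
boundary-element TFM solvers at desk scale; no multipole acceleration is
used or needed for ≤ 10³ elements.

**Inverse problem.** min‖Mt − u‖² + λ‖t‖², solved through an
eigendecomposition of MᵀM — numerically equivalent to the normal
equations, but making a λ sweep O(n²) per value, which the L-curve needs.
λ = 0 with a rank-deficient operator raises rather than silently
minimum-norm-solving.

**L-curve.** λ is selected at the maximum-curvature corner of
(log residual norm, log solution norm) across a grid of ≥ 10 values
spanning ≥ 4 decades, with curvature computed on spline-smoothed curves
parametrized by log₁₀ λ. Degenerate case: if the residual already climbs
within the first grid step there is no noise-floor plateau (noiseless or
under-sampled data), the corner lies below the grid, and the smallest
grid value is returned with a warning. On forward-generated dipole scenes
with 5% displacement noise (noise sd = 5% of the peak displacement) the corner lands within ~0.7 decades of the
truth-error-minimizing λ, and within-band total-force errors are ≤ ~8%.

**PTV.** Beads are localized in the relaxed image (LoG + Gaussian fit,
σ = 1.5 px; the point-source goodness-of-fit filter is disabled for
beads, since dense bead fields overlap and would be over-rejected — bad
vectors are handled downstream). A 17-px template around each bead is
matched in the stressed image within a ±50 px window by normalized cross-
correlation. Sub-pixel refinement fits a 3-point parabola per axis to the
**raw cross-covariance** rather than the NCC: per-window normalization
breaks the symmetry of the correlation around the true peak and biases
the interpolation, while the covariance reduces to a symmetric
autocovariance for pure shifts (making integer-shift recovery exact). A
correlation peak below 0.5, or sitting on the border of the (possibly
clipped) search window, marks the vector invalid. Outliers are flagged by
the normalized median test (8 nearest neighbors, threshold 2.0,
ε = 0.1 in vector units) and replaced by the local median.

**Readouts.** Total force = Σ|t| × element area over mesh nodes inside
the cell mask (Pa·μm²; 1000 Pa·μm² = 1 nN). Per-class adhesion traction
interpolates |t| bilinearly at adhesion positions and averages within
class; positions outside the mesh are excluded and logged.

## Statistics and reporting

Condition comparisons use the two-sided Mann–Whitney U test: the exact
null distribution when both samples have n ≤ 8 and no ties, the
tie-corrected normal approximation otherwise; fully tied samples return
p = 1 explicitly. Significance stars follow ** p < 10⁻², *** p < 10⁻⁵,
**** p < 10⁻¹⁰, with no multiple-testing correction (stated in the
report footer). Box statistics use the Tukey convention (1.5 × IQR
whiskers). The activation index AI = (F − F₀)/(F_max − F₀) is undefined
when F_max = F₀ and raises rather than returning NaN.

## Synthetic scenes: what they emulate, and what they don't

The movie generator renders adhesions as elliptical Gaussians (PSF
σ = 2.1 px convolved with a footprint ellipse grown linearly to its final
area), on a constant-plus-gradient background, with Poisson shot noise
and Gaussian read noise applied last from a single seeded generator —
generation is a pure function of (config, truths, seed), byte-identical
under the same seed. Defaults follow the imaging conditions the pipeline
targets: 20 s frame interval, 0.086 μm/px, 16-bit output.

Two intensity time-courses are available. The movie renderer defaults to
the saturating form I_plateau(1 − e^(−k_a t)) followed by exponential
decay; the `exponential` form I₀e^(k_a t) (capped at the plateau) is
exactly log-linear and is the fixture used for validating the rate
estimator, since the estimator's model *is* log-linear growth. Recovery
results on saturating traces are therefore conservative near the plateau
— one reason the adaptive window exists.

The TFM generator scatters beads uniformly (default density 0.02
beads/px² — dense enough that each 17-px template holds several beads
and is a unique fingerprint; the sparse densities sometimes quoted for
bead substrates are below what cross-correlation PTV can use), displaces
them only through the forward model evaluated at their reference
positions, and renders both images with the same PSF model. Maximum
displacement is recorded and warned about if it exceeds half the template.

Not emulated, hence not validated by passing tests: cell-shape
morphodynamics and adhesion treadmilling, photobleaching, 3-D PSF
structure, camera fixed-pattern noise, gel thickness (the half-space
model overestimates compliance for thin gels), substrate drift between
stressed and relaxed acquisitions, and focal drift. Results on real data
depend on these; the synthetic benchmarks bound algorithmic error only.

## Problem sizes

The validation suite and the acceptance script use scene sizes chosen to
exercise every code path at full fidelity while staying desk-scale:
256²-px detection frames with 50 planted spots, 30 trajectories × 20
frames for linking, 500 seeded traces for kinetics Monte-Carlo, and a
24×24-element mesh (64×64 μm) with 800 beads for TFM round trips. Errors
at these sizes are dominated by noise and discretization, not by scale;
larger meshes change runtimes, not conclusions.
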