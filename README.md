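# adhesiontfm

Quantitative analysis of focal adhesion dynamics and cellular traction
forces from fluorescence microscopy, with a synthetic-scene generator for
end-to-end validation against known ground truth.

## What it does

Cells attach to their substrate through integrin adhesions that nucleate
as diffraction-limited **nascent adhesions (NAs)**, mature into **focal
complexes (FCs, 0.24–0.6 μm²)** and **focal adhesions (FAs, ≥ 0.6 μm²)**,
and transmit contractile force into the substrate. This package implements
the image-analysis chain that turns two-channel TIRF time-lapse movies
(e.g. paxillin-mRuby plus a GFP-tagged adaptor) and TFM bead-image pairs
into the standard readouts of that biology:

- **Detection** — nascent adhesions as point sources: scale-normalized
  Laplacian-of-Gaussian filtering, local maxima above a robust
  noise-derived threshold, sub-pixel localization by fixed-width isotropic
  Gaussian fitting (σ = 2.1 px ≈ 180 nm), and a goodness-of-fit filter on
  the fit residuals (p = 0.05).
- **Segmentation** — FC/FA regions from Gaussian-filtered,
  background-subtracted paxillin frames, thresholded by a blend of Otsu's
  and Rosin's criteria; components classified by area (≤ 0.2 μm²
  discarded, ≥ 0.24 μm² FC, ≥ 0.6 μm² FA) with second-moment ellipse
  shape descriptors (eccentricity = minor/major axis ratio).
- **Tracking** — frame-to-frame linear assignment on squared
  displacement with gap closing; per-frame status per trajectory
  (`BA`/`NA`/`FC`/`FA`) by overlap with the segmentation; lifetimes
  ((frames spanned) × Δt, censored tracks excluded), nucleation and
  maturation fractions.
- **Kinetics** — assembly and disassembly rate constants as the slope of
  ln(I/I₀) (resp. ln(I₀/I)) versus time over the window maximizing the
  adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2), with the 0.3 adjusted-R²
  threshold flagging noise-like traces. Rates in min⁻¹, natural log.
- **TFM** — bead displacements by normalized-cross-correlation particle
  tracking (17-px templates, 50-px search, parabolic sub-pixel peak),
  normalized-median outlier correction, and traction reconstruction on a
  5 kPa elastic half-space (Boussinesq–Cerruti Green's function,
  analytically integrated over piecewise-constant mesh elements):
  min‖Mt − u‖² + λ‖t‖² with λ at the L-curve corner. Readouts: total
  force ∫|t| dA over the cell mask and mean traction per adhesion class.
- **Reporting** — per-condition medians/quartiles, two-sided
  Mann–Whitney U comparisons (exact for n ≤ 8) with the figure-legend
  star conventions, and the flow-cytometry activation index
  AI = (F − F₀)/(F_max − F₀).

Everything is exercised on synthetic scenes whose ground truth (adhesion
positions, rates, traction fields, bead displacements) is known
exhaustively, so each stage's accuracy is measurable rather than assumed.

## Worked example

Simulate a two-channel movie with two adhesions of known kinetics, then
recover the assembly rate of one of them:

```python
import numpy as np
import adhesiontfm as at

cfg = at.SceneConfig(frame_count=40, image_shape=(128, 128), rng_seed=7)
truths = [
    at.AdhesionGroundTruth(id=0, x=40.0, y=44.0, nucleation_frame=2,
                           assembly_rate=0.6, plateau_intensity=300.0,
                           disassembly_start_frame=22, disassembly_rate=0.4,
                           intensity_shape="exponential", initial_intensity=40.0),
    at.AdhesionGroundTruth(id=1, x=88.0, y=70.0, nucleation_frame=0,
                           assembly_rate=0.4, plateau_intensity=250.0,
                           disassembly_start_frame=30, disassembly_rate=0.2,
                           final_area_um2=0.8, elongation=0.5),
]
pax, gfp, _ = at.generate_adhesion_scene(cfg, truths)
dets = at.detect_movie(pax)
tracks = at.link_detections(dets, search_radius=3.0, max_gap=2)
segs = at.segment_movie(pax)
for tr in tracks:
    at.assign_status(tr, segs, pax.shape)
tr = max((t for t in tracks if len(t.points) >= 10),
         key=lambda t: len(t.points))
times = np.array([p[0] for p in tr.points]) * cfg.frame_interval
amps = np.array([p[3] for p in tr.points])
fit = at.assembly_rate(at.IntensityTrace(tr.id, times, amps))
print(f"track {tr.id}: assembly k = {fit.rate_constant:.3f} min^-1 "
      f"(adjusted R^2 = {fit.adjusted_r2:.3f}, window = {fit.window})")
```

prints

```
track 1: assembly k = 0.607 min^-1 (adjusted R^2 = 0.993, window = (0, 10))
```

— the detector/tracker/fitter chain recovers the planted 0.6 min⁻¹
assembly rate to about 1% from the rendered, Poisson-noised movie; the
selected window (samples 0–10) stops where exponential growth ends.

A traction round trip on a contractile dipole (two opposing 300 Pa
tangential patches on a 64×64 μm mesh, 800 beads, 5% displacement noise):

```python
mesh = at.RectMesh.from_extent(64.0, 24)
truth, mask = at.make_dipole_traction(mesh, (32, 32), 16.0, 4.0, 300.0)
substrate = at.ElasticSubstrate()          # 5 kPa, nu = 0.5
rng = np.random.default_rng(0)
beads = np.column_stack([rng.uniform(0, 64, 800), rng.uniform(0, 64, 800)])
u = at.boussinesq_forward(truth, substrate, beads)
noisy = at.DisplacementField(beads, u.vectors + rng.normal(
    0, 0.05 * np.abs(u.vectors).max(), u.vectors.shape))
lam = at.select_regularization(noisy, substrate, mesh,
                               np.logspace(-10, -2, 25))
rec = at.reconstruct_traction(noisy, substrate, mesh, lam)
print(f"lambda (L-corner) = {lam:.2e}")
print(f"total force: truth {at.total_force(truth, mask)/1000:.1f} nN, "
      f"reconstructed {at.total_force(rec, mask)/1000:.1f} nN")
```

prints

```
lambda (L-corner) = 2.94e-07
total force: truth 57.2 nN, reconstructed 59.0 nN
```

— a 3% total-force error at the automatically selected regularization.

## Command line

```sh
adhesiontfm simulate-movie --seed 1 --out-dir scene      # movie + ground truth
adhesiontfm simulate-tfm   --seed 1 --out-dir tfm_scene  # bead image pair
adhesiontfm run-all --config run.yaml --seed 1 --out-dir results
```

`run-all` executes detection → segmentation → tracking → kinetics →
TFM → report on synthetic or user-supplied TIFFs and writes CSV tables
(with unit/convention headers) plus a manifest of config hash, seed and
output checksums; a rerun with the same config is bit-identical.

## Conventions

Coordinates are 0-based with origin at the center of pixel (0, 0) and
x = column. Rates are per minute (natural log); lifetimes are
(frames spanned) × frame interval; tractions are Pa and forces Pa·μm²
(1000 Pa·μm² = 1 nN). See `docs/methods.md` for the models, parameter
defaults, and known limitations.
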