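"""Synthetic adhesion movies and TFM scenes with exhaustively known truth.

The adhesion generator emulates what a TIRF time-lapse of paxillin-marked
adhesions looks like to the downstream pipeline: diffraction-limited
puncta that nucleate, brighten, plateau and decay with known rate
constants, optionally growing into elongated FA-scale footprints, on a
constant-plus-gradient background with Poisson shot noise and Gaussian
read noise. The default frame interval is 20 s and the default PSF width
2.1 px (~180 nm at 0.086 μm/px).

Two intensity time-course shapes are available: ``"saturating"``
(I_plateau·(1 − e^{−k_a t}) rise, then exponential decay), the shape used
when rendering movies, and ``"exponential"`` (I₀·e^{k_a t} capped at the
plateau), which is exactly log-linear and is the natural fixture for the
rate estimator. Scene generation is a pure function of (config, truths):
the same seed reproduces the scene bit for bit.

The TFM generator scatters fiducial beads on the substrate surface,
displaces them with the elastic half-space forward model under a known
traction field, and renders stressed/relaxed bead images. Bead density
defaults to 0.02 beads/px²; the generator never moves a bead except
through the forward model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import ImageStack
from .tfm import (DisplacementField, ElasticSubstrate, RectMesh,
                  TractionField, boussinesq_forward)


@dataclass
class SceneConfig:
    """Acquisition and noise parameters of a synthetic adhesion movie."""

    frame_count: int = 30
    frame_interval: float = 20.0     # s
    pixel_size: float = 0.086        # μm/px
    psf_sigma: float = 2.1           # px
    image_shape: tuple[int, int] = (128, 128)
    background_level: float = 100.0  # photons
    background_gradient: float = 0.0  # photons/pixel along x
    poisson_gain: float = 1.0        # 0 disables shot noise
    read_noise_sd: float = 2.0       # 0 disables read noise
    rng_seed: int = 0

    def __post_init__(self):
        if self.frame_count < 2:
            raise ValueError("frame_count must be ≥ 2")
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")


@dataclass
class AdhesionGroundTruth:
    """Known life history of one synthetic adhesion."""

    id: int
    x: float                         # px
    y: float                         # px
    nucleation_frame: int
    assembly_rate: float             # min⁻¹
    plateau_intensity: float         # photons (peak amplitude)
    disassembly_start_frame: int
    disassembly_rate: float          # min⁻¹
    final_area_um2: float = 0.0      # 0 → purely punctate
    elongation: float = 1.0          # minor/major axis ratio
    gfp_coupling: float = 1.0
    orientation: float = 0.0         # rad, major-axis angle
    vx: float = 0.0                  # px/frame drift
    vy: float = 0.0
    intensity_shape: str = "saturating"  # or "exponential"
    initial_intensity: float = 10.0  # photons; I₀ of the exponential shape

    def __post_init__(self):
        if self.assembly_rate <= 0 or self.disassembly_rate <= 0:
            raise ValueError("rates must be positive")
        if self.disassembly_start_frame <= self.nucleation_frame:
            raise ValueError("disassembly must start after nucleation")

    def position_at(self, frame: int) -> tuple[float, float]:
        dt = frame - self.nucleation_frame
        return self.x + self.vx * dt, self.y + self.vy * dt

    def intensity_at(self, t_since_nucleation_s: float,
                     frame_interval: float = 20.0) -> float:
        """Analytic peak intensity at a time (s) after nucleation."""
        t = t_since_nucleation_s
        if t < 0:
            return 0.0
        ka = self.assembly_rate / 60.0
        kd = self.disassembly_rate / 60.0
        t_switch = ((self.disassembly_start_frame - self.nucleation_frame)
                    * frame_interval)

        def rise(tt):
            if self.intensity_shape == "exponential":
                return min(self.initial_intensity * np.exp(ka * tt),
                           self.plateau_intensity)
            return self.plateau_intensity * (1 - np.exp(-ka * tt))

        if t <= t_switch:
            return float(rise(t))
        return float(rise(t_switch) * np.exp(-kd * (t - t_switch)))

    def area_at(self, frame: int) -> float:
        """Footprint area (μm²), ramping linearly to the final area."""
        if frame < self.nucleation_frame or self.final_area_um2 <= 0:
            return 0.0
        span = max(self.disassembly_start_frame - self.nucleation_frame, 1)
        frac = min((frame - self.nucleation_frame) / span, 1.0)
        return self.final_area_um2 * frac


def _render_spot(img, x, y, amp, sigma_major, sigma_minor, theta):
    """Add an elliptical Gaussian of peak amplitude ``amp`` to ``img``."""
    if amp <= 0:
        return
    smax = max(sigma_major, sigma_minor)
    half = int(np.ceil(5 * smax))
    r0, r1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
    c0, c1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, img.shape[0]), min(c1, img.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    yy, xx = np.mgrid[r0c:r1c, c0c:c1c].astype(float)
    dx, dy = xx - x, yy - y
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    img[r0c:r1c, c0c:c1c] += amp * np.exp(
        -(u ** 2 / (2 * sigma_major ** 2) + v ** 2 / (2 * sigma_minor ** 2)))


def _footprint_sigmas(area_um2, elongation, pixel_size, psf_sigma):
    """Per-axis render widths: PSF convolved with the elliptical footprint."""
    if area_um2 <= 0:
        return psf_sigma, psf_sigma
    # footprint modeled as a Gaussian ellipse of area π σ_a σ_b
    sig_prod = area_um2 / np.pi / pixel_size ** 2  # σa·σb in px²
    s_major = np.sqrt(sig_prod / elongation)
    s_minor = s_major * elongation
    return (np.sqrt(psf_sigma ** 2 + s_major ** 2),
            np.sqrt(psf_sigma ** 2 + s_minor ** 2))


def generate_adhesion_scene(config: SceneConfig,
                            truths: list[AdhesionGroundTruth]):
    """Render a two-channel adhesion movie from ground-truth life histories.

    Returns ``(paxillin, gfp, truths)`` ImageStacks; the GFP channel is the
    same adhesions scaled by each truth's ``gfp_coupling``. Noise (Poisson
    with ``poisson_gain``, then Gaussian read noise) is applied last, from
    a generator seeded by ``config.rng_seed``. Ground truth is returned
    unmodified.
    """
    h, w = config.image_shape
    for i, tr in enumerate(truths):
        if not (0 <= tr.x < w and 0 <= tr.y < h):
            raise ValueError(f"adhesion {i} (id={tr.id}) placed outside frame")
    xgrad = np.arange(w)[None, :] * config.background_gradient
    channels = {}
    rng = np.random.default_rng(config.rng_seed)
    for label, coupling in (("paxillin", None), ("GFP", "gfp")):
        frames = np.empty((config.frame_count, h, w))
        for f in range(config.frame_count):
            img = np.full((h, w), float(config.background_level)) + xgrad
            t = f * config.frame_interval
            for tr in truths:
                amp = tr.intensity_at(
                    t - tr.nucleation_frame * config.frame_interval,
                    config.frame_interval)
                if coupling == "gfp":
                    amp *= tr.gfp_coupling
                sa, sb = _footprint_sigmas(tr.area_at(f), tr.elongation,
                                           config.pixel_size, config.psf_sigma)
                px, py = tr.position_at(f)
                _render_spot(img, px, py, amp, sa, sb, tr.orientation)
            frames[f] = img
        if config.poisson_gain > 0:
            frames = rng.poisson(frames / config.poisson_gain) * config.poisson_gain
        if config.read_noise_sd > 0:
            frames = frames + rng.normal(0.0, config.read_noise_sd, frames.shape)
        channels[label] = ImageStack(frames.astype(float), config.pixel_size,
                                     config.frame_interval, label)
    return channels["paxillin"], channels["GFP"], truths


# ------------------------------------------------------------------ traces

def synthetic_trace(track_id: int, k_assembly: float, k_disassembly: float,
                    n_points: int, changepoint: int, dt: float = 20.0,
                    i0: float = 50.0, noise_cv: float = 0.0,
                    rng: np.random.Generator | None = None,
                    channel: str = "paxillin"):
    """Pure-exponential rise/decay intensity trace for kinetics fixtures.

    I(t) = i0·e^{k_a t} for the first ``changepoint`` samples then
    exponential decay at ``k_d`` (rates per minute, Δt in seconds).
    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` is applied when positive.
    """
    from .kinetics import IntensityTrace
    t = np.arange(n_points) * dt
    tm = t / 60.0
    i_vals = np.where(tm <= tm[changepoint],
                      i0 * np.exp(k_assembly * tm),
                      i0 * np.exp(k_assembly * tm[changepoint])
                      * np.exp(-k_disassembly * (tm - tm[changepoint])))
    if noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        sigma = np.sqrt(np.log(1 + noise_cv ** 2))
        i_vals = i_vals * rng.lognormal(-sigma ** 2 / 2, sigma, i_vals.shape)
    return IntensityTrace(track_id, t, i_vals, channel)


# ------------------------------------------------------------------ TFM

@dataclass
class TfmSceneTruth:
    """Ground truth of a synthetic TFM scene."""

    traction_truth: TractionField
    bead_positions_reference: np.ndarray  # (N, 2) μm
    bead_positions_stressed: np.ndarray   # (N, 2) μm
    cell_mask: np.ndarray                 # bool per mesh node
    substrate: ElasticSubstrate
    metadata: dict = field(default_factory=dict)


def make_gaussian_patch_traction(mesh: RectMesh, patches,
                                 substrate_mask_margin: float = 3.0
                                 ) -> tuple[TractionField, np.ndarray]:
    """Traction field from tangential Gaussian patches on a mesh.

    ``patches`` is a list of ``(cx, cy, sigma_um, tx, ty)``; the returned
    cell mask covers nodes within ``substrate_mask_margin`` sigmas of any
    patch center.
    """
    nodes = mesh.nodes
    t = np.zeros_like(nodes)
    mask = np.zeros(len(nodes), dtype=bool)
    for cx, cy, sig, tx, ty in patches:
        r2 = (nodes[:, 0] - cx) ** 2 + (nodes[:, 1] - cy) ** 2
        g = np.exp(-r2 / (2 * sig ** 2))
        t[:, 0] += tx * g
        t[:, 1] += ty * g
        mask |= r2 <= (substrate_mask_margin * sig) ** 2
    return TractionField(mesh, t), mask


def make_dipole_traction(mesh: RectMesh, center: tuple[float, float],
                         separation: float, sigma_um: float,
                         magnitude_pa: float):
    """Two opposing tangential Gaussian patches (a contractile dipole)."""
    cx, cy = center
    patches = [(cx - separation / 2, cy, sigma_um, magnitude_pa, 0.0),
               (cx + separation / 2, cy, sigma_um, -magnitude_pa, 0.0)]
    return make_gaussian_patch_traction(mesh, patches)


def generate_tfm_scene(traction_truth: TractionField,
                       substrate: ElasticSubstrate, bead_count: int,
                       seed: int, pixel_size: float = 0.1,
                       bead_sigma_px: float = 1.5,
                       bead_amplitude: float = 500.0,
                       background: float = 100.0,
                       template_size: int = 17,
                       cell_mask: np.ndarray | None = None):
    """Scatter beads, displace them with the forward model, render images.

    Returns ``(scene: TfmSceneTruth, stressed_image, relaxed_image)``.
    Bead reference positions are uniform over the mesh extent; stressed
    positions are reference + forward displacement evaluated at the
    reference positions (beads outside the cell mask still feel the
    elastic far field — they are never displaced independently). The
    maximum displacement is recorded in the scene metadata, with a warning
    if it exceeds half the PTV template size.
    """
    mesh = traction_truth.mesh
    rng = np.random.default_rng(seed)
    x0, x1 = mesh.x[0] - mesh.spacing / 2, mesh.x[-1] + mesh.spacing / 2
    y0, y1 = mesh.y[0] - mesh.spacing / 2, mesh.y[-1] + mesh.spacing / 2
    ref = np.column_stack([rng.uniform(x0, x1, bead_count),
                           rng.uniform(y0, y1, bead_count)])
    disp = boussinesq_forward(traction_truth, substrate, ref)
    stressed_pos = ref + disp.vectors
    max_disp_um = float(np.max(np.hypot(*disp.vectors.T))) if bead_count else 0.0
    meta = {"max_displacement_um": max_disp_um,
            "max_displacement_px": max_disp_um / pixel_size}
    if max_disp_um / pixel_size > template_size / 2:
        meta["warning"] = "max displacement exceeds half the template size"
        warnings.warn(meta["warning"], RuntimeWarning)
    shape = (int(np.ceil((y1 - y0) / pixel_size)),
             int(np.ceil((x1 - x0) / pixel_size)))

    def render(points):
        img = np.full(shape, background)
        for x, y in points:
            _render_spot(img, (x - x0) / pixel_size, (y - y0) / pixel_size,
                         bead_amplitude, bead_sigma_px, bead_sigma_px, 0.0)
        return img

    relaxed = render(ref)
    stressed = render(stressed_pos)
    if cell_mask is None:
        cell_mask = traction_truth.magnitude > 1e-9 * max(
            traction_truth.magnitude.max(), 1e-30)
    meta.update(pixel_size=pixel_size, origin=(x0, y0), seed=seed)
    scene = TfmSceneTruth(traction_truth, ref, stressed_pos,
                          np.asarray(cell_mask, bool), substrate, meta)
    return scene, stressed, relaxed


# ------------------------------------------------------------------ I/O

def write_scene(out_dir, paxillin: ImageStack, gfp: ImageStack,
                truths: list[AdhesionGroundTruth], config: SceneConfig):
    """Write a generated scene: TIFF per channel, truths as JSON + CSV."""
    import pandas as pd
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paxillin.to_tiff(out / "paxillin.tif")
    gfp.to_tiff(out / "gfp.tif")
    clean = []
    for tr in truths:
        d = asdict(tr)
        d.pop("_t_disassembly_s", None)
        clean.append(d)
    (out / "ground_truth.json").write_text(
        json.dumps({"config": asdict(config), "adhesions": clean}, indent=1))
    rows = []
    for tr in truths:
        for f in range(config.frame_count):
            x, y = tr.position_at(f)
            rows.append({"id": tr.id, "frame": f, "x_px": x, "y_px": y,
                         "intensity": tr.intensity_at(
                             (f - tr.nucleation_frame) * config.frame_interval,
                             config.frame_interval)})
    pd.DataFrame(rows).to_csv(out / "ground_truth_frames.csv", index=False)
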