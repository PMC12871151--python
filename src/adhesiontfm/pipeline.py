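"""Orchestration: configuration, staged execution, manifests and CSV I/O.

A run is driven by a single :class:`RunConfig` (YAML/JSON round-trippable;
unknown keys are rejected). Stages write plain CSV tables with a ``#``
header comment block carrying units and conventions, plus a manifest
recording the config hash, seed, package version and the SHA-256 of every
stage output. Deterministic stages are bit-identical across reruns of the
same config; on a stage failure the partial results are preserved and the
manifest marks the failure point.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ImageStack
from . import detection, kinetics, segmentation, synthetic, tfm, tracking

logger = logging.getLogger(__name__)

_HEADER = """\
# adhesiontfm v{version} — {table}
# coordinates: 0-based, origin at center of pixel (0,0), x = column
# lifetime convention: (frames spanned) x frame_interval; log base: natural
# rates: per minute; positions: pixels unless stated; tractions: Pa
"""


def _dump_csv(df: pd.DataFrame, path: Path, table: str) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER.format(version=__version__, table=table))
        df.to_csv(fh, index=False)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run. Unknown keys are rejected."""

    out_dir: str = "run_output"
    seed: int = 0
    # inputs: either paths to TIFFs or a synthetic scene specification
    paxillin_tiff: str | None = None
    gfp_tiff: str | None = None
    pixel_size: float = 0.086
    frame_interval: float = 20.0
    scene: dict = field(default_factory=dict)       # SceneConfig overrides
    adhesions: list = field(default_factory=list)   # AdhesionGroundTruth dicts
    detection: dict = field(default_factory=lambda: {
        "sigma": 2.1, "alpha": 0.05, "gof_alpha": 0.05})
    segmentation: dict = field(default_factory=lambda: {
        "threshold_mode": "mean", "smooth_sigma": 1.0,
        "background_radius": 15})
    tracking: dict = field(default_factory=lambda: {
        "search_radius": 3.0, "max_gap": 2, "min_frames": 3})
    kinetics: dict = field(default_factory=lambda: {"r2_threshold": 0.3})
    tfm: dict = field(default_factory=dict)  # empty → stage skipped
    condition_label: str = "condition"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config_hash": config.config_hash(),
                "seed": config.seed, "stages": {}, "failed_stage": None}
    config.to_yaml(out / "config.yaml")

    def record(stage: str, *paths: Path):
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}
        _write_manifest(out, manifest)

    stage = "input"
    try:
        pax, gfp = _load_or_simulate(config, out)
        record("input", out / "paxillin.tif", out / "gfp.tif")

        stage = "detection"
        dcfg = config.detection
        dets = detection.detect_movie(pax, sigma=dcfg["sigma"],
                                      alpha=dcfg["alpha"],
                                      gof_alpha=dcfg["gof_alpha"])
        det_df = pd.DataFrame([{"frame": d.frame, "x": d.x, "y": d.y,
                                "amplitude": d.amplitude,
                                "background": d.background,
                                "gof_p": d.gof_pvalue} for d in dets])
        _dump_csv(det_df, out / "detections.csv", "detections")
        record("detection", out / "detections.csv")

        stage = "segmentation"
        scfg = config.segmentation
        segs = segmentation.segment_movie(
            pax, mode=scfg["threshold_mode"],
            smooth_sigma=scfg["smooth_sigma"],
            background_radius=scfg["background_radius"])
        seg_df = pd.DataFrame([{"frame": r.frame, "label": r.label,
                                "area_um2": r.area, "class": r.adhesion_class,
                                "major_um": r.major_axis,
                                "minor_um": r.minor_axis,
                                "ecc_ratio": r.eccentricity_ratio,
                                "x": r.centroid[0], "y": r.centroid[1]}
                               for frame in segs for r in frame])
        _dump_csv(seg_df, out / "regions.csv", "segmented regions")
        record("segmentation", out / "regions.csv")

        stage = "tracking"
        tcfg = config.tracking
        tracks = tracking.link_detections(dets,
                                          search_radius=tcfg["search_radius"],
                                          max_gap=tcfg["max_gap"])
        for tr in tracks:
            tracking.assign_status(tr, segs, pax.shape)
        life = tracking.compute_lifetimes(tracks, pax.frame_interval,
                                          frame_count=len(pax))
        fractions = tracking.nucleation_and_maturation(
            tracks, min_frames=tcfg["min_frames"])
        track_df = pd.DataFrame([
            {"track_id": tr.id, "frame": f, "x": x, "y": y, "amplitude": a,
             "status": s}
            for tr in tracks
            for (f, x, y, a), s in zip(tr.points, tr.status_sequence)])
        _dump_csv(track_df, out / "tracks.csv", "tracks (long format)")
        (out / "track_stats.json").write_text(json.dumps({
            "na_lifetimes_s": life.na_lifetimes,
            "fa_lifetimes_s": life.fa_lifetimes,
            "n_left_censored": life.n_left_censored,
            "n_right_censored": life.n_right_censored,
            **{k: v for k, v in fractions.items()}}, indent=1))
        record("tracking", out / "tracks.csv", out / "track_stats.json")

        stage = "kinetics"
        kin_rows = []
        thr = config.kinetics["r2_threshold"]
        for tr in tracks:
            if len(tr.points) < kinetics.MIN_WINDOW:
                continue
            times = np.array([p[0] for p in tr.points]) * pax.frame_interval
            amps = np.array([p[3] for p in tr.points])
            trace = kinetics.IntensityTrace(tr.id, times, amps, "paxillin")
            for fit_fn in (kinetics.assembly_rate, kinetics.disassembly_rate):
                fit = fit_fn(trace, r2_threshold=thr)
                if fit.failed:
                    continue
                kin_rows.append({"track_id": tr.id, "channel": "paxillin",
                                 "phase": fit.phase,
                                 "rate_per_min": fit.rate_constant,
                                 "adjusted_r2": fit.adjusted_r2,
                                 "window_start": fit.window[0],
                                 "window_end": fit.window[1],
                                 "passed_filter": fit.passed_filter})
        _dump_csv(pd.DataFrame(kin_rows), out / "kinetics.csv",
                  "assembly/disassembly rate constants")
        record("kinetics", out / "kinetics.csv")

        stage = "tfm"
        if config.tfm:
            tfm_df = _run_tfm_stage(config)
            _dump_csv(tfm_df, out / "tfm_nodes.csv", "traction mesh nodes")
            record("tfm", out / "tfm_nodes.csv")

        stage = "report"
        from .report import ConditionSummary, build_report
        samples = {
            "assembly_rate_per_min": [r["rate_per_min"] for r in kin_rows
                                      if r["phase"] == "assembly"
                                      and r["passed_filter"]],
            "disassembly_rate_per_min": [r["rate_per_min"] for r in kin_rows
                                         if r["phase"] == "disassembly"
                                         and r["passed_filter"]],
            "na_lifetime_s": life.na_lifetimes,
            "fa_lifetime_s": life.fa_lifetimes,
        }
        summary, _ = build_report([ConditionSummary(
            config.condition_label, samples, n_cells=1)])
        _dump_csv(summary, out / "report.csv", "condition summary")
        record("report", out / "report.csv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _load_or_simulate(config: RunConfig, out: Path):
    if config.paxillin_tiff:
        pax = ImageStack.from_tiff(config.paxillin_tiff, config.pixel_size,
                                   config.frame_interval, "paxillin")
        gfp = (ImageStack.from_tiff(config.gfp_tiff, config.pixel_size,
                                    config.frame_interval, "GFP")
               if config.gfp_tiff else pax)
    else:
        scene_cfg = synthetic.SceneConfig(
            **{"rng_seed": config.seed, **config.scene})
        truths = ([synthetic.AdhesionGroundTruth(**a)
                   for a in config.adhesions]
                  or _default_truths(scene_cfg))
        pax, gfp, _ = synthetic.generate_adhesion_scene(scene_cfg, truths)
    pax.to_tiff(out / "paxillin.tif")
    gfp.to_tiff(out / "gfp.tif")
    return pax, gfp


def _default_truths(cfg: synthetic.SceneConfig):
    """A small default population spanning NA-only and maturing adhesions."""
    rng = np.random.default_rng(cfg.rng_seed + 1)
    h, w = cfg.image_shape
    truths = []
    for i in range(12):
        nuc = int(rng.integers(0, max(cfg.frame_count // 3, 1)))
        dis = nuc + int(rng.integers(6, max(cfg.frame_count // 2, 7)))
        truths.append(synthetic.AdhesionGroundTruth(
            id=i, x=float(rng.uniform(15, w - 15)),
            y=float(rng.uniform(15, h - 15)), nucleation_frame=nuc,
            assembly_rate=float(rng.uniform(0.2, 0.8)),
            plateau_intensity=float(rng.uniform(150, 400)),
            disassembly_start_frame=dis,
            disassembly_rate=float(rng.uniform(0.2, 0.8)),
            final_area_um2=float(rng.choice([0.0, 0.0, 0.4, 0.9])),
            elongation=float(rng.uniform(0.4, 1.0))))
    return truths


def _run_tfm_stage(config: RunConfig) -> pd.DataFrame:
    """Synthetic TFM stage: forward scene, PTV, outlier filter, inversion."""
    from .tfm import ElasticSubstrate, RectMesh
    c = {"extent_um": 64.0, "n_elements": 24, "patch_sigma_um": 4.0,
         "patch_separation_um": 16.0, "magnitude_pa": 300.0,
         "bead_count": 800, "noise_fraction": 0.05,
         "youngs_modulus": 5000.0, "poisson_ratio": 0.5, **config.tfm}
    mesh = RectMesh.from_extent(c["extent_um"], c["n_elements"])
    substrate = ElasticSubstrate(c["youngs_modulus"], c["poisson_ratio"])
    truth, mask = synthetic.make_dipole_traction(
        mesh, (c["extent_um"] / 2, c["extent_um"] / 2),
        c["patch_separation_um"], c["patch_sigma_um"], c["magnitude_pa"])
    rng = np.random.default_rng(config.seed + 7)
    beads = np.column_stack([
        rng.uniform(0, c["extent_um"], c["bead_count"]),
        rng.uniform(0, c["extent_um"], c["bead_count"])])
    disp = tfm.boussinesq_forward(truth, substrate, beads)
    noise_sd = c["noise_fraction"] * float(np.abs(disp.vectors).max())
    noisy = tfm.DisplacementField(
        beads, disp.vectors + rng.normal(0, noise_sd, disp.vectors.shape))
    filtered = tfm.filter_displacement_outliers(noisy)
    lam = tfm.select_regularization(filtered, substrate, mesh,
                                    np.logspace(-10, -2, 25))
    rec = tfm.reconstruct_traction(filtered, substrate, mesh, lam)
    nodes = mesh.nodes
    return pd.DataFrame({"x_um": nodes[:, 0], "y_um": nodes[:, 1],
                         "tx_pa": rec.stress_vectors[:, 0],
                         "ty_pa": rec.stress_vectors[:, 1],
                         "truth_tx_pa": truth.stress_vectors[:, 0],
                         "truth_ty_pa": truth.stress_vectors[:, 1],
                         "in_cell_mask": mask,
                         "lambda": lam})
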