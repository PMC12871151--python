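"""Traction force microscopy: PTV displacements and regularized inversion.

The substrate is modeled as a linear-elastic half-space (Boussinesq–Cerruti
problem). A tangential traction t applied on the surface produces a surface
displacement

    u_i(x) = ∫ G_ij(x − x') t_j(x') dA',
    G_ij(r) = (1 + ν) / (π E r) [ (1 − ν) δ_ij + ν r_i r_j / r² ],

with E the Young's modulus and ν the Poisson ratio. Traction is
discretized as piecewise-constant vectors on a regular quadrilateral mesh;
the Green's tensor is integrated analytically over each rectangular
element (all four kernel integrals ∬1/r, ∬x²/r³, ∬y²/r³, ∬xy/r³ have
closed forms), so the forward operator is well defined even at points
inside an element — the pointwise kernel is never evaluated at its
singularity.

The inverse problem min ‖M t − u‖² + λ‖t‖² is solved through an
eigendecomposition of MᵀM, which makes sweeping the regularization
parameter cheap; λ is chosen at the maximum-curvature corner of the
L-curve (log residual norm vs log solution norm), computed on a
spline-smoothed curve.

Bead displacements are measured by particle tracking velocimetry:
normalized cross-correlation of a template around each bead of the relaxed
image inside a search window of the stressed image, with 3-point parabolic
sub-pixel peak interpolation and a normalized-median-test outlier filter.

Units: positions and displacements in μm, tractions in Pa, forces in
Pa·μm² (1000 Pa·μm² = 1 nN). The gel is treated as infinitely thick; a
finite gel would stiffen the apparent response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate
from scipy.spatial import cKDTree
from skimage.feature import match_template

from .detection import detect_point_sources

logger = logging.getLogger(__name__)


@dataclass
class ElasticSubstrate:
    """Linear-elastic half-space; default 5 kPa incompressible silicone."""

    youngs_modulus: float = 5000.0  # Pa
    poisson_ratio: float = 0.5

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


@dataclass
class RectMesh:
    """Regular rectangular mesh of piecewise-constant traction elements."""

    x: np.ndarray       # element-center x coordinates, μm, shape (nx,)
    y: np.ndarray       # element-center y coordinates, μm, shape (ny,)
    spacing: float      # μm (square elements)

    @classmethod
    def from_extent(cls, extent: float, n: int, origin: float = 0.0) -> "RectMesh":
        h = extent / n
        c = origin + (np.arange(n) + 0.5) * h
        return cls(c, c.copy(), h)

    @property
    def nodes(self) -> np.ndarray:
        """(N, 2) element centers, x fastest... row-major over (y, x)."""
        xx, yy = np.meshgrid(self.x, self.y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def n_nodes(self) -> int:
        return self.x.size * self.y.size

    @property
    def element_area(self) -> float:
        return self.spacing ** 2


@dataclass
class DisplacementField:
    positions: np.ndarray        # (N, 2), μm
    vectors: np.ndarray          # (N, 2), μm
    outlier_mask: np.ndarray = None     # bool per vector
    correlation_peak: np.ndarray = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, float))
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(len(self.positions), dtype=bool)
        if self.correlation_peak is None:
            self.correlation_peak = np.ones(len(self.positions))


@dataclass
class TractionField:
    mesh: RectMesh
    stress_vectors: np.ndarray   # (N, 2), Pa, aligned to mesh.nodes
    regularization_parameter: float = 0.0
    residual_norm: float = float("nan")
    solution_norm: float = float("nan")
    metadata: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.stress_vectors[:, 0], self.stress_vectors[:, 1])

    def magnitude_grid(self) -> np.ndarray:
        return self.magnitude.reshape(self.mesh.y.size, self.mesh.x.size)


# ---------------------------------------------------------------- forward

def _corner_eval(f, x1, x2, y1, y2):
    return f(x2, y2) - f(x1, y2) - f(x2, y1) + f(x1, y1)


def _element_integrals(dx, dy, h):
    """Analytic integrals of the kernel terms over a square element.

    ``dx, dy`` are (eval − element-center) offsets; returns
    (∬1/r, ∬x²/r³, ∬xy/r³, ∬y²/r³) over the element, where (x, y) is the
    eval-to-source offset. Valid for evaluation points inside the element
    (the improper integrals converge).
    """
    x1, x2 = dx - h / 2, dx + h / 2
    y1, y2 = dy - h / 2, dy + h / 2
    tiny = 1e-12 * h

    def r(x, y):
        return np.sqrt(x * x + y * y)

    def xlog(y, x):  # y * ln(x + r), safe at the log singularity
        arg = np.maximum(x + r(x, y), tiny)
        return y * np.log(arg)

    fxx = _corner_eval(lambda x, y: xlog(y, x), x1, x2, y1, y2)
    fyy = _corner_eval(lambda x, y: xlog(x, y), x1, x2, y1, y2)
    fxy = _corner_eval(lambda x, y: -r(x, y), x1, x2, y1, y2)
    return fxx + fyy, fxx, fxy, fyy


def assemble_forward_matrix(mesh: RectMesh, eval_points: np.ndarray,
                            substrate: ElasticSubstrate) -> np.ndarray:
    """Forward operator M mapping element tractions (Pa) to displacements (μm).

    Block layout: rows [u_x …, u_y …], columns [t_x …, t_y …].
    """
    pts = np.atleast_2d(np.asarray(eval_points, float))
    nodes = mesh.nodes
    dx = pts[:, 0:1] - nodes[None, :, 0]
    dy = pts[:, 1:2] - nodes[None, :, 1]
    f1, fxx, fxy, fyy = _element_integrals(dx, dy, mesh.spacing)
    nu, e_mod = substrate.poisson_ratio, substrate.youngs_modulus
    c = (1 + nu) / (np.pi * e_mod)
    axx = c * ((1 - nu) * f1 + nu * fxx)
    ayy = c * ((1 - nu) * f1 + nu * fyy)
    axy = c * nu * fxy
    n_e, n_t = pts.shape[0], nodes.shape[0]
    m_mat = np.empty((2 * n_e, 2 * n_t))
    m_mat[:n_e, :n_t] = axx
    m_mat[:n_e, n_t:] = axy
    m_mat[n_e:, :n_t] = axy
    m_mat[n_e:, n_t:] = ayy
    return m_mat


def boussinesq_forward(traction: TractionField, substrate: ElasticSubstrate,
                       eval_points: np.ndarray) -> DisplacementField:
    """Surface displacement produced by a piecewise-constant traction field."""
    pts = np.atleast_2d(np.asarray(eval_points, float))
    m_mat = assemble_forward_matrix(traction.mesh, pts, substrate)
    t = np.concatenate([traction.stress_vectors[:, 0],
                        traction.stress_vectors[:, 1]])
    u = m_mat @ t
    n = pts.shape[0]
    return DisplacementField(pts, np.column_stack([u[:n], u[n:]]))


# ---------------------------------------------------------------- inverse

def reconstruct_traction(field: DisplacementField, substrate: ElasticSubstrate,
                         mesh: RectMesh, lam: float,
                         _cache: dict | None = None) -> TractionField:
    """Tikhonov-regularized traction reconstruction.

    Solves min ‖M t − u‖² + λ‖t‖² through the eigendecomposition of MᵀM
    (numerically equivalent to the normal equations but stable across a
    λ sweep). Outlier-masked vectors are excluded from the data.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    valid = ~field.outlier_mask
    pts = field.positions[valid]
    u = np.concatenate([field.vectors[valid, 0], field.vectors[valid, 1]])
    if _cache is not None and "evals" in _cache:
        m_mat = _cache["m"]
        evals, evecs, mtu = _cache["evals"], _cache["evecs"], _cache["mtu"]
    else:
        m_mat = assemble_forward_matrix(mesh, pts, substrate)
        mtm = m_mat.T @ m_mat
        evals, evecs = np.linalg.eigh(mtm)
        mtu = m_mat.T @ u
        if _cache is not None:
            _cache.update(m=m_mat, evals=evals, evecs=evecs, mtu=mtu)
    if lam == 0 and evals.min() < 1e-12 * evals.max():
        raise np.linalg.LinAlgError(
            "forward matrix is rank-deficient; use lambda > 0")
    t = evecs @ ((evecs.T @ mtu) / (evals + lam))
    resid = float(np.linalg.norm(m_mat @ t - u))
    n = mesh.n_nodes
    tf = TractionField(mesh, np.column_stack([t[:n], t[n:]]),
                       regularization_parameter=lam,
                       residual_norm=resid,
                       solution_norm=float(np.linalg.norm(t)),
                       metadata={"lambda": lam, "mesh_spacing": mesh.spacing,
                                 "youngs_modulus": substrate.youngs_modulus,
                                 "poisson_ratio": substrate.poisson_ratio})
    return tf


def select_regularization(field: DisplacementField, substrate: ElasticSubstrate,
                          mesh: RectMesh, lambda_grid: np.ndarray,
                          return_details: bool = False):
    """L-curve corner selection of the regularization parameter.

    Computes (log residual norm, log solution norm) across ``lambda_grid``
    (≥ 10 values spanning ≥ 4 decades), smooths both as splines in log10 λ
    and returns the λ of maximum signed curvature. If no proper corner
    exists (monotone curvature), a warning is issued and the curvature
    maximum is returned anyway.
    """
    grid = np.sort(np.asarray(lambda_grid, float))
    if grid.size < 10:
        raise ValueError("lambda grid must contain at least 10 values")
    if np.log10(grid[-1] / grid[0]) < 4:
        raise ValueError("lambda grid must span at least 4 decades")
    cache: dict = {}
    rho, eta = [], []
    for lam in grid:
        tf = reconstruct_traction(field, substrate, mesh, lam, _cache=cache)
        rho.append(tf.residual_norm)
        eta.append(tf.solution_norm)
    s = np.log10(grid)
    lx = np.log(np.maximum(rho, 1e-300))
    ly = np.log(np.maximum(eta, 1e-300))
    # a noise floor shows as a residual plateau at the small-λ end of the
    # curve; if the residual already climbs within the first grid step the
    # corner lies below the grid (noiseless or under-sampled data)
    if lx[1] - lx[0] > np.log(1.5):
        warnings.warn("no residual plateau at the small-lambda end; the "
                      "L-corner degenerates — returning the grid minimum",
                      RuntimeWarning)
        if return_details:
            return float(grid[0]), {
                "lambda_grid": grid, "residual_norms": np.array(rho),
                "solution_norms": np.array(eta), "curvature_max": 0.0,
                "flagged": True}
        return float(grid[0])
    k = min(3, grid.size - 1)
    spx = interpolate.UnivariateSpline(s, lx, k=k, s=len(s) * 1e-6)
    spy = interpolate.UnivariateSpline(s, ly, k=k, s=len(s) * 1e-6)
    sf = np.linspace(s[0], s[-1], 400)
    x1, x2 = spx.derivative(1)(sf), spx.derivative(2)(sf)
    y1, y2 = spy.derivative(1)(sf), spy.derivative(2)(sf)
    denom = (x1 ** 2 + y1 ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = np.where(denom > 0, (x1 * y2 - y1 * x2) / denom, 0.0)
    idx = int(np.argmax(curvature))
    corner = float(10 ** sf[idx])
    flagged = curvature[idx] <= 0 or idx in (0, len(sf) - 1)
    if flagged:
        warnings.warn("L-curve has no well-defined corner; returning the "
                      "curvature maximum anyway", RuntimeWarning)
    if return_details:
        return corner, {"lambda_grid": grid, "residual_norms": np.array(rho),
                        "solution_norms": np.array(eta),
                        "curvature_max": float(curvature[idx]),
                        "flagged": bool(flagged)}
    return corner


# ---------------------------------------------------------------- PTV

def _parabolic_offset(cm, c0, cp):
    denom = cm - 2 * c0 + cp
    if denom >= -1e-12:  # not a proper maximum
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -1.0, 1.0))


def ptv_displacement(stressed: np.ndarray, relaxed: np.ndarray,
                     template_size: int = 17, max_displacement: int = 50,
                     corr_floor: float = 0.5, bead_sigma: float = 1.5,
                     pixel_size: float = 1.0,
                     detection_alpha: float = 0.05,
                     detection_gof_alpha: float = 0.0) -> DisplacementField:
    """Per-bead displacement by normalized cross-correlation template matching.

    Beads are localized in the relaxed image; a ``template_size`` patch
    around each is matched within a ±``max_displacement`` window of the
    stressed image. Sub-pixel peak position by 3-point parabolic
    interpolation per axis. Vectors whose correlation peak falls below
    ``corr_floor`` are marked invalid (candidate outliers). Output
    positions/vectors are scaled to μm by ``pixel_size``.

    The point-source goodness-of-fit filter is disabled by default for
    bead localization (dense bead fields overlap, which the isotropic
    single-emitter model rejects); spurious beads are caught downstream by
    the correlation floor and the normalized-median outlier test.
    """
    stressed = np.asarray(stressed, float)
    relaxed = np.asarray(relaxed, float)
    if stressed.shape != relaxed.shape:
        raise ValueError("stressed and relaxed images must share a shape")
    beads = detect_point_sources(relaxed, sigma=bead_sigma,
                                 alpha=detection_alpha,
                                 gof_alpha=detection_gof_alpha)
    half = template_size // 2
    pos, vec, mask, peaks = [], [], [], []
    for det in beads:
        r, c = int(round(det.y)), int(round(det.x))
        if not (half <= r < relaxed.shape[0] - half
                and half <= c < relaxed.shape[1] - half):
            continue
        template = relaxed[r - half:r + half + 1, c - half:c + half + 1]
        r0 = max(r - half - max_displacement, 0)
        c0 = max(c - half - max_displacement, 0)
        r1 = min(r + half + max_displacement + 1, stressed.shape[0])
        c1 = min(c + half + max_displacement + 1, stressed.shape[1])
        region = stressed[r0:r1, c0:c1]
        if region.shape[0] < template_size or region.shape[1] < template_size:
            continue
        ncc = match_template(region, template)
        pr, pc = np.unravel_index(np.argmax(ncc), ncc.shape)
        peak = float(ncc[pr, pc])
        # a peak on the correlation-map border means the true match may lie
        # outside the (clipped) search window — treat as invalid
        on_border = (pr in (0, ncc.shape[0] - 1)
                     or pc in (0, ncc.shape[1] - 1))
        # sub-pixel refinement on the raw cross-covariance: unlike the
        # per-window-normalized NCC it is symmetric around the true peak
        # (it reduces to an autocovariance for a pure shift)
        tz = template - template.mean()
        cov = np.full((3, 3), -np.inf)
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                r_i, c_j = pr + i, pc + j
                if (0 <= r_i <= region.shape[0] - template.shape[0]
                        and 0 <= c_j <= region.shape[1] - template.shape[1]):
                    win = region[r_i:r_i + template.shape[0],
                                 c_j:c_j + template.shape[1]]
                    cov[i + 1, j + 1] = float(np.sum(tz * win))
        dr = dc = 0.0
        if peak < 1.0 - 1e-9:  # NCC of exactly 1 means a perfect lattice match
            if np.isfinite(cov[0, 1]) and np.isfinite(cov[2, 1]):
                dr = _parabolic_offset(cov[0, 1], cov[1, 1], cov[2, 1])
            if np.isfinite(cov[1, 0]) and np.isfinite(cov[1, 2]):
                dc = _parabolic_offset(cov[1, 0], cov[1, 1], cov[1, 2])
        uy = (r0 + pr + half + dr) - r
        ux = (c0 + pc + half + dc) - c
        pos.append((det.x, det.y))
        vec.append((ux, uy))
        peaks.append(peak)
        mask.append(peak < corr_floor or on_border)
    if not pos:
        return DisplacementField(np.empty((0, 2)), np.empty((0, 2)),
                                 np.empty(0, bool), np.empty(0))
    return DisplacementField(np.array(pos) * pixel_size,
                             np.array(vec) * pixel_size,
                             np.array(mask), np.array(peaks))


def filter_displacement_outliers(field: DisplacementField,
                                 threshold: float = 2.0,
                                 n_neighbors: int = 8,
                                 eps: float = 0.1) -> DisplacementField:
    """Normalized-median-test outlier correction of a displacement field.

    For each vector the residual to the median of its ``n_neighbors``
    nearest neighbors is normalized by the median residual of those
    neighbors (plus ``eps``, in vector units, to absorb measurement
    noise); vectors whose normalized fluctuation exceeds ``threshold``
    — and vectors already marked invalid — are replaced by the local
    median. Replacements are recorded in ``outlier_mask``.
    """
    n = len(field.positions)
    if n < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 vectors")
    tree = cKDTree(field.positions)
    _, idx = tree.query(field.positions, k=n_neighbors + 1)
    neigh = idx[:, 1:]
    vec = field.vectors
    med = np.median(vec[neigh], axis=1)                     # (n, 2)
    resid_neigh = np.abs(vec[neigh] - med[:, None, :])      # (n, k, 2)
    norm_scale = np.median(resid_neigh, axis=1) + eps
    fluct = np.abs(vec - med) / norm_scale
    flag = np.sqrt((fluct ** 2).sum(axis=1)) > threshold
    flag |= field.outlier_mask
    new_vec = vec.copy()
    new_vec[flag] = med[flag]
    return DisplacementField(field.positions.copy(), new_vec,
                             flag, field.correlation_peak.copy())


# ---------------------------------------------------------------- readouts

def total_force(traction: TractionField, cell_mask: np.ndarray) -> float:
    """Total force in Pa·μm²: Σ |t| × element area over masked nodes."""
    mask = np.asarray(cell_mask, bool).ravel()
    if mask.shape[0] != traction.mesh.n_nodes:
        raise ValueError("cell_mask must align to the traction mesh nodes")
    if not mask.any():
        raise ValueError("empty cell mask")
    return float(traction.magnitude[mask].sum() * traction.mesh.element_area)


def adhesion_traction(traction: TractionField, positions: np.ndarray,
                      classes: list[str]) -> dict[str, float]:
    """Mean traction magnitude per adhesion class at adhesion positions (μm).

    Magnitude is bilinearly interpolated on the traction mesh; positions
    outside the mesh are excluded (logged).
    """
    mesh = traction.mesh
    interp = interpolate.RegularGridInterpolator(
        (mesh.y, mesh.x), traction.magnitude_grid(),
        bounds_error=False, fill_value=None)
    positions = np.atleast_2d(np.asarray(positions, float))
    per_class: dict[str, list[float]] = {}
    for (x, y), cls in zip(positions, classes):
        if not (mesh.x[0] - mesh.spacing <= x <= mesh.x[-1] + mesh.spacing
                and mesh.y[0] - mesh.spacing <= y <= mesh.y[-1] + mesh.spacing):
            logger.info("adhesion at (%.1f, %.1f) μm outside mesh; excluded",
                        x, y)
            continue
        per_class.setdefault(cls, []).append(float(interp((y, x))))
    return {cls: float(np.mean(v)) for cls, v in per_class.items()}
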