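"""Traction force microscopy: forward model, inversion, PTV, readouts."""

import numpy as np
import pytest

from adhesiontfm.synthetic import (make_dipole_traction,
                                   make_gaussian_patch_traction)
from adhesiontfm.tfm import (DisplacementField, ElasticSubstrate, RectMesh,
                             TractionField, adhesion_traction,
                             boussinesq_forward, filter_displacement_outliers,
                             ptv_displacement, reconstruct_traction,
                             select_regularization, total_force,
                             _element_integrals)
from conftest import render_spots


SUB = ElasticSubstrate()  # 5 kPa, ν = 0.5


def small_mesh(extent=32.0, n=12):
    return RectMesh.from_extent(extent, n)


def dipole_scene(seed, noise=0.05, extent=64.0, n_mesh=24, n_beads=800,
                 magnitude=300.0):
    """Forward-generated dipole displacements at the standard scene scale."""
    mesh = RectMesh.from_extent(extent, n_mesh)
    truth, mask = make_dipole_traction(mesh, (extent / 2, extent / 2),
                                       extent / 4, extent / 16, magnitude)
    rng = np.random.default_rng(seed)
    beads = np.column_stack([rng.uniform(0, extent, n_beads),
                             rng.uniform(0, extent, n_beads)])
    clean = boussinesq_forward(truth, SUB, beads)
    vec = clean.vectors
    if noise:
        vec = vec + rng.normal(0, noise * np.abs(vec).max(), vec.shape)
    return mesh, truth, mask, DisplacementField(beads, vec)


class TestForwardModel:
    def test_element_integrals_match_numeric_quadrature(self):
        """Closed-form kernel integrals vs adaptive quadrature (oracle)."""
        from scipy import integrate
        h = 2.0
        for dx, dy in [(5.3, 2.1), (2.0, 0.0), (0.7, 0.3)]:
            f1, fxx, fxy, fyy = _element_integrals(
                np.array(dx), np.array(dy), h)
            for got, fn in [
                    (f1, lambda x, y: 1 / np.hypot(x, y)),
                    (fxx, lambda x, y: x * x / np.hypot(x, y) ** 3),
                    (fxy, lambda x, y: x * y / np.hypot(x, y) ** 3),
                    (fyy, lambda x, y: y * y / np.hypot(x, y) ** 3)]:
                want, _ = integrate.dblquad(
                    lambda sy, sx: fn(dx - sx, dy - sy),
                    -h / 2, h / 2, -h / 2, h / 2)
                assert float(got) == pytest.approx(want, rel=1e-8)

    def test_zero_traction_zero_displacement(self):
        mesh = small_mesh()
        tf = TractionField(mesh, np.zeros((mesh.n_nodes, 2)))
        disp = boussinesq_forward(tf, SUB, [(10.0, 10.0), (20.0, 5.0)])
        assert np.allclose(disp.vectors, 0.0)

    def test_far_field_decays_as_one_over_r(self):
        mesh = small_mesh(extent=8.0, n=8)  # 1 μm elements
        tf, _ = make_gaussian_patch_traction(mesh, [(4.0, 4.0, 0.5, 100.0, 0.0)])
        rs = np.array([40.0, 80.0, 160.0])  # ≥ 10 patch widths
        pts = [(4.0 + r, 4.0) for r in rs]
        mags = np.hypot(*boussinesq_forward(tf, SUB, pts).vectors.T)
        for i in range(len(rs) - 1):
            ratio = mags[i] / mags[i + 1]
            assert ratio == pytest.approx(rs[i + 1] / rs[i], rel=0.05)

    def test_doubling_modulus_halves_displacement(self):
        mesh = small_mesh()
        tf, _ = make_dipole_traction(mesh, (16, 16), 8.0, 2.0, 200.0)
        pts = [(10.0, 12.0), (22.0, 18.0)]
        u1 = boussinesq_forward(tf, SUB, pts).vectors
        u2 = boussinesq_forward(tf, ElasticSubstrate(2 * SUB.youngs_modulus,
                                                     SUB.poisson_ratio),
                                pts).vectors
        assert np.allclose(u2, u1 / 2, rtol=1e-12)

    def test_betti_reciprocity(self):
        """Displacement at B from a patch at A equals the exchange, numerically."""
        mesh = small_mesh()
        a, b = (10.0, 10.0), (22.0, 20.0)
        ta = np.zeros((mesh.n_nodes, 2))
        tb = np.zeros((mesh.n_nodes, 2))
        ia = np.argmin(np.linalg.norm(mesh.nodes - a, axis=1))
        ib = np.argmin(np.linalg.norm(mesh.nodes - b, axis=1))
        ta[ia] = (100.0, 0.0)
        tb[ib] = (100.0, 0.0)
        u_ab = boussinesq_forward(TractionField(mesh, ta), SUB,
                                  [mesh.nodes[ib]]).vectors[0, 0]
        u_ba = boussinesq_forward(TractionField(mesh, tb), SUB,
                                  [mesh.nodes[ia]]).vectors[0, 0]
        assert u_ab == pytest.approx(u_ba, rel=1e-9)


class TestReconstruction:
    def _scene(self, seed=0, n_beads=400, noise=0.0):
        mesh = small_mesh()
        truth, mask = make_dipole_traction(mesh, (16, 16), 8.0, 2.0, 300.0)
        rng = np.random.default_rng(seed)
        beads = np.column_stack([rng.uniform(0, 32, n_beads),
                                 rng.uniform(0, 32, n_beads)])
        disp = boussinesq_forward(truth, SUB, beads)
        if noise:
            sd = noise * np.abs(disp.vectors).max()
            disp = DisplacementField(
                beads, disp.vectors + rng.normal(0, sd, disp.vectors.shape))
        return mesh, truth, mask, disp

    def test_noiseless_round_trip_within_5pct_rms(self):
        mesh, truth, _, disp = self._scene()
        rec = reconstruct_traction(disp, SUB, mesh, 1e-12)
        err = (np.linalg.norm(rec.stress_vectors - truth.stress_vectors)
               / np.linalg.norm(truth.stress_vectors))
        assert err < 0.05

    def test_ridge_limit_shrinks_solution(self):
        mesh, _, _, disp = self._scene()
        norms = [reconstruct_traction(disp, SUB, mesh, lam).solution_norm
                 for lam in (1e-8, 1e-4, 1e0, 1e4)]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_zero_displacement_zero_traction(self):
        mesh, *_ = self._scene()
        disp = DisplacementField(np.array([[5.0, 5.0], [20.0, 25.0],
                                           [12.0, 8.0]]), np.zeros((3, 2)))
        rec = reconstruct_traction(disp, SUB, mesh, 1e-4)
        assert np.allclose(rec.stress_vectors, 0.0)

    def test_linearity_in_data(self):
        mesh, _, _, disp = self._scene()
        rec1 = reconstruct_traction(disp, SUB, mesh, 1e-6)
        rec3 = reconstruct_traction(
            DisplacementField(disp.positions, 3.0 * disp.vectors),
            SUB, mesh, 1e-6)
        assert np.allclose(rec3.stress_vectors, 3 * rec1.stress_vectors,
                           rtol=1e-9, atol=1e-9)

    def test_rank_deficient_lambda_zero_raises(self):
        mesh = small_mesh()
        disp = DisplacementField(np.array([[5.0, 5.0], [20.0, 25.0]]),
                                 np.array([[0.1, 0.0], [0.0, 0.1]]))
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            reconstruct_traction(disp, SUB, mesh, 0.0)

    def test_residual_and_solution_norm_monotone_in_lambda(self):
        mesh, _, _, disp = self._scene(noise=0.05)
        grid = np.logspace(-10, -2, 12)
        cache = {}
        rhos, etas = [], []
        for lam in grid:
            rec = reconstruct_traction(disp, SUB, mesh, lam, _cache=cache)
            rhos.append(rec.residual_norm)
            etas.append(rec.solution_norm)
        assert all(a <= b + 1e-12 for a, b in zip(rhos, rhos[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(etas, etas[1:]))

    def test_round_trip_total_force_never_inflates(self):
        """Tikhonov shrinkage: recovered total force ≤ 110% of truth."""
        mesh, truth, mask, disp = self._scene()
        for lam in (1e-12, 1e-8, 1e-6):
            rec = reconstruct_traction(disp, SUB, mesh, lam)
            assert total_force(rec, mask) <= 1.1 * total_force(truth, mask)


class TestLCurve:
    def test_corner_within_decade_of_truth_optimal(self):
        mesh, truth, _, disp = dipole_scene(seed=42, noise=0.05)
        grid = np.logspace(-10, -2, 25)
        lam = select_regularization(disp, SUB, mesh, grid)
        cache = {}
        errs = [np.linalg.norm(
            reconstruct_traction(disp, SUB, mesh, l, _cache=cache)
            .stress_vectors - truth.stress_vectors) for l in grid]
        l_opt = grid[int(np.argmin(errs))]
        assert abs(np.log10(lam / l_opt)) <= 1.0

    def test_noiseless_corner_sits_at_small_lambda(self):
        import warnings as _w
        mesh, truth, _, disp = dipole_scene(seed=0, noise=0.0)
        grid = np.logspace(-10, -2, 15)
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # corner may degenerate
            lam = select_regularization(disp, SUB, mesh, grid)
        assert lam <= grid[len(grid) // 2]

    def test_small_grid_rejected(self):
        mesh, = (small_mesh(),)
        disp = DisplacementField(np.zeros((4, 2)), np.zeros((4, 2)))
        with pytest.raises(ValueError):
            select_regularization(disp, SUB, mesh, np.logspace(-4, -2, 3))


class TestPTV:
    # realistic bead density (~0.01/px²): templates hold several beads,
    # so each 17-px fingerprint is unique within the search window
    def _bead_points(self, rng, n=800, shape=(256, 256)):
        return [(rng.uniform(15, shape[1] - 15), rng.uniform(15, shape[0] - 15),
                 300.0) for _ in range(n)]

    def test_identical_images_zero_vectors(self, rng):
        img = render_spots((256, 256), self._bead_points(rng), sigma=1.5,
                           background=100.0)
        field = ptv_displacement(img, img)
        assert len(field.positions) > 200
        assert np.allclose(field.vectors, 0.0, atol=1e-9)

    def test_integer_shift_recovered_exactly(self, rng):
        pts = self._bead_points(rng)
        img = render_spots((256, 256), pts, sigma=1.5, background=100.0)
        shifted = render_spots((256, 256),
                               [(x + 3, y - 2, a) for x, y, a in pts],
                               sigma=1.5, background=100.0)
        field = ptv_displacement(shifted, img)
        good = ~field.outlier_mask
        assert good.sum() > 200
        assert np.allclose(field.vectors[good, 0], 3.0, atol=1e-6)
        assert np.allclose(field.vectors[good, 1], -2.0, atol=1e-6)

    def test_subpixel_shift_recovered(self, rng):
        pts = self._bead_points(rng)
        img0 = render_spots((256, 256), pts, sigma=1.5, background=100.0)
        img1 = render_spots((256, 256), [(x + 0.3, y, a) for x, y, a in pts],
                            sigma=1.5, background=100.0)
        field = ptv_displacement(img1, img0)
        good = ~field.outlier_mask
        assert abs(field.vectors[good, 0].mean() - 0.3) < 0.1
        assert abs(field.vectors[good, 1].mean()) < 0.1


class TestOutlierFilter:
    def _smooth_field(self, rng, n=200):
        pos = np.column_stack([rng.uniform(0, 100, n), rng.uniform(0, 100, n)])
        vec = np.column_stack([0.005 * pos[:, 0], 0.003 * pos[:, 1]])
        return pos, vec

    def test_planted_outliers_flagged(self, rng):
        pos, vec = self._smooth_field(rng)
        n_bad = 10  # 5%
        bad = rng.choice(len(pos), n_bad, replace=False)
        vec = vec.copy()
        vec[bad] += rng.uniform(3, 6, (n_bad, 2))
        out = filter_displacement_outliers(DisplacementField(pos, vec))
        assert out.outlier_mask[bad].sum() >= 0.9 * n_bad
        false_flags = out.outlier_mask.sum() - out.outlier_mask[bad].sum()
        assert false_flags < 0.02 * (len(pos) - n_bad) + 1
        assert np.all(np.isfinite(out.vectors))

    def test_smooth_field_untouched(self, rng):
        pos, vec = self._smooth_field(rng)
        out = filter_displacement_outliers(DisplacementField(pos, vec))
        assert out.outlier_mask.sum() == 0
        assert np.allclose(out.vectors, vec)

    def test_wild_vector_in_constant_field_replaced(self, rng):
        pos = np.column_stack([rng.uniform(0, 50, 80), rng.uniform(0, 50, 80)])
        vec = np.full((80, 2), 1.0)
        vec[17] = (25.0, -30.0)
        out = filter_displacement_outliers(DisplacementField(pos, vec))
        assert out.outlier_mask[17]
        assert np.allclose(out.vectors[17], (1.0, 1.0))


class TestReadouts:
    def test_total_force_arithmetic(self):
        mesh = RectMesh.from_extent(10.0, 10)  # 100 μm², 1 μm² elements
        t = np.zeros((100, 2))
        t[:, 0] = 100.0  # uniform 100 Pa
        tf = TractionField(mesh, t)
        force = total_force(tf, np.ones(100, bool))
        assert force == pytest.approx(10000.0)  # = 10 nN

    def test_zero_field_zero_force(self):
        mesh = RectMesh.from_extent(10.0, 10)
        tf = TractionField(mesh, np.zeros((100, 2)))
        assert total_force(tf, np.ones(100, bool)) == 0.0

    def test_empty_mask_raises(self):
        mesh = RectMesh.from_extent(10.0, 10)
        tf = TractionField(mesh, np.zeros((100, 2)))
        with pytest.raises(ValueError):
            total_force(tf, np.zeros(100, bool))

    def test_adhesion_on_uniform_patch_reads_patch_value(self):
        mesh = RectMesh.from_extent(20.0, 20)
        t = np.zeros((400, 2))
        nodes = mesh.nodes
        patch = (np.abs(nodes[:, 0] - 10) < 4) & (np.abs(nodes[:, 1] - 10) < 4)
        t[patch, 0] = 50.0
        tf = TractionField(mesh, t)
        res = adhesion_traction(tf, [(10.0, 10.0), (2.0, 18.0)],
                                ["FA", "NA"])
        assert res["FA"] == pytest.approx(50.0, rel=1e-6)
        assert res["NA"] == pytest.approx(0.0, abs=1e-9)

    def test_class_ordering_follows_planted_traction(self):
        mesh = RectMesh.from_extent(20.0, 20)
        tf, _ = make_gaussian_patch_traction(mesh, [(6.0, 6.0, 2.0, 200.0, 0.0)])
        res = adhesion_traction(
            tf, [(6.0, 6.0), (6.5, 6.0), (16.0, 16.0), (17.0, 15.0)],
            ["FA", "FA", "NA", "NA"])
        assert res["FA"] > res["NA"]

    def test_dipole_round_trip_force_within_10pct_at_snr10(self):
        mesh, truth, mask, clean = dipole_scene(seed=5, noise=0.0)
        rng = np.random.default_rng(55)
        sd = np.sqrt(np.mean(clean.vectors ** 2)) / 10  # SNR 10
        disp = DisplacementField(
            clean.positions,
            clean.vectors + rng.normal(0, sd, clean.vectors.shape))
        lam = select_regularization(disp, SUB, mesh,
                                    np.logspace(-10, -2, 25))
        rec = reconstruct_traction(disp, SUB, mesh, lam)
        assert total_force(rec, mask) == pytest.approx(
            total_force(truth, mask), rel=0.10)
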