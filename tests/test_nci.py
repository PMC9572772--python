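"""Promolecular densities, RDG, Hessian eigenvalues, NCI scatter, cube I/O."""

import numpy as np
import pytest

from ctclab.constants import BOHR_PER_ANGSTROM
from ctclab.cube import (export_cube, export_scatter_csv, read_cube,
                         read_scatter_csv)
from ctclab.geometry import MolecularGeometry, read_xyz, write_xyz
from ctclab.nci import (RDG_PREFACTOR, RDGField, compute_rdg,
                        eigvals3_symmetric, hbond_trough_depth, nci_analysis,
                        nci_scatter, signed_density)
from ctclab.promolecular import density_at, promolecular_density
from ctclab.synth import gen_hbond_dimer


def single_atom(el="H"):
    return MolecularGeometry((el,), np.zeros((1, 3)))


class TestPromolecularDensity:
    def test_single_atom_spherically_symmetric(self):
        geom = single_atom("H")
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                        [0, 0, 1], [0, 0, -1]], dtype=float)
        rho, _, _ = density_at(geom, pts)
        assert np.ptp(rho) < 1e-12

    def test_promolecule_is_sum_of_atoms(self):
        geom = MolecularGeometry(("O", "H"),
                                 np.array([[0.0, 0, 0], [1.5, 0, 0]]))
        pts = np.random.default_rng(1).uniform(-2, 3, size=(20, 3))
        rho_pair, _, _ = density_at(geom, pts)
        rho_o, _, _ = density_at(single_atom("O"), pts)
        rho_h, _, _ = density_at(
            MolecularGeometry(("H",), np.array([[1.5, 0, 0]])), pts)
        np.testing.assert_allclose(rho_pair, rho_o + rho_h, rtol=1e-12)

    def test_each_atom_integrates_to_electron_count(self):
        # radial quadrature of the shipped shell densities
        r = np.linspace(1e-6, 40.0, 200001)
        for el, z in [("H", 1), ("C", 6), ("N", 7), ("O", 8), ("Cl", 17)]:
            pts = np.zeros((len(r), 3))
            pts[:, 0] = r
            rho, _, _ = density_at(single_atom(el), pts)
            total = np.trapezoid(4 * np.pi * r ** 2 * rho, r)
            assert total == pytest.approx(z, rel=1e-4)

    def test_analytic_gradient_matches_finite_differences(self, water_dimer):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-2, 6, size=(100, 3))
        rho, grad, _ = density_at(water_dimer, pts)
        h = 1e-4
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            rp, _, _ = density_at(water_dimer, pts + e)
            rm, _, _ = density_at(water_dimer, pts - e)
            num = (rp - rm) / (2 * h)
            rel = np.abs(grad[:, k] - num) / np.maximum(np.abs(num), 1e-12)
            assert rel.max() < 1e-5

    def test_hessian_trace_equals_laplacian_finite_difference(self, water_dimer):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1, 5, size=(30, 3))
        rho, _, hess = density_at(water_dimer, pts)
        lap = hess[:, 0] + hess[:, 1] + hess[:, 2]
        h = 1e-4
        num = -6 * rho / h ** 2 * 0.0
        num = np.zeros(len(pts))
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            rp, _, _ = density_at(water_dimer, pts + e)
            rm, _, _ = density_at(water_dimer, pts - e)
            num += (rp - 2 * rho + rm) / h ** 2
        np.testing.assert_allclose(lap, num, rtol=1e-4)

    def test_positive_and_decaying_far_field(self, water_dimer):
        far = np.array([[20.0, 0, 0], [25.0, 0, 0], [30.0, 0, 0]])
        rho, _, _ = density_at(water_dimer, far)
        assert np.all(rho > 0)
        assert rho[0] > rho[1] > rho[2]

    def test_grid_encloses_atoms_with_margin(self, water_dimer):
        field = promolecular_density(water_dimer, spacing_bohr=0.4, margin_A=2.0)
        coords = water_dimer.coords_bohr
        margin = 2.0 * BOHR_PER_ANGSTROM
        lo = field.grid.origin_bohr
        hi = lo + field.grid.axis_steps_bohr * (np.array(field.grid.shape) - 1)
        assert np.all(lo <= coords.min(axis=0) - margin + 1e-9)
        assert np.all(hi >= coords.max(axis=0) + margin - 0.4)
        assert np.all(field.grid.values > 0)

    def test_unsupported_element_named_in_error(self):
        with pytest.raises(ValueError, match="Fe"):
            MolecularGeometry(("Fe",), np.zeros((1, 3)))

    def test_slater_fallback_model_runs(self):
        rho, grad, hess = density_at(single_atom("O"),
                                     np.array([[1.0, 0, 0]]), model="slater")
        assert rho[0] > 0


class TestRDG:
    def test_single_exponential_closed_form(self):
        # rho = exp(-2r): RDG = (3 pi^2)^(-1/3) e^(2r/3)
        r = np.array([0.0, 0.5, 1.0, 2.0])
        rho = np.exp(-2 * r)
        grad = np.zeros((3, len(r)))
        grad[0] = -2 * np.exp(-2 * r)       # radial direction magnitude
        s = compute_rdg(rho, grad)
        expected = (3 * np.pi ** 2) ** (-1 / 3) * np.exp(2 * r / 3)
        np.testing.assert_allclose(s, expected, rtol=1e-12)
        assert s[0] == pytest.approx(0.3233, abs=2e-4)

    def test_uniform_density_gives_zero(self):
        rho = np.full(10, 0.3)
        grad = np.zeros((3, 10))
        assert np.all(compute_rdg(rho, grad) == 0.0)

    def test_dimensionless_scaling_invariance(self):
        # norm-preserving rescale rho -> lam^3 rho(lam r) maps the RDG to
        # RDG(lam r): the index is dimensionless
        lam = 1.7
        r = np.linspace(0.1, 3.0, 50)
        rho_l = lam ** 3 * np.exp(-2 * lam * r)
        grad_l = np.zeros((3, 50))
        grad_l[0] = -2 * lam ** 4 * np.exp(-2 * lam * r)
        s_l = compute_rdg(rho_l, grad_l)
        # RDG of e^(-2r) evaluated at lam*r
        expected = (3 * np.pi ** 2) ** (-1 / 3) * np.exp(2 * lam * r / 3)
        np.testing.assert_allclose(s_l, expected, rtol=1e-12)


class TestEigenvalues:
    def test_matches_lapack_on_random_symmetric(self):
        rng = np.random.default_rng(11)
        comp = rng.normal(size=(6, 200))
        lam = eigvals3_symmetric(comp)
        mats = np.zeros((200, 3, 3))
        xx, yy, zz, xy, xz, yz = comp
        mats[:, 0, 0], mats[:, 1, 1], mats[:, 2, 2] = xx, yy, zz
        mats[:, 0, 1] = mats[:, 1, 0] = xy
        mats[:, 0, 2] = mats[:, 2, 0] = xz
        mats[:, 1, 2] = mats[:, 2, 1] = yz
        ref = np.linalg.eigvalsh(mats)
        np.testing.assert_allclose(lam.T, ref, atol=1e-12)

    def test_ascending_order_and_trace_identity(self, water_dimer):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-1, 5, size=(50, 3))
        _, _, hess = density_at(water_dimer, pts)
        lam = eigvals3_symmetric(hess.T)
        assert np.all(lam[0] <= lam[1] + 1e-12)
        assert np.all(lam[1] <= lam[2] + 1e-12)
        trace = hess[:, 0] + hess[:, 1] + hess[:, 2]
        np.testing.assert_allclose(lam.sum(axis=0), trace, rtol=1e-8)

    def test_degenerate_isotropic_matrix(self):
        comp = np.array([[2.0], [2.0], [2.0], [0.0], [0.0], [0.0]])
        lam = eigvals3_symmetric(comp)
        np.testing.assert_allclose(lam, 2.0)


class TestSignedDensity:
    def test_spherical_decay_has_negative_tangential_curvature(self):
        # rho = e^(-2r) at r = 1 along x: lambda2 = tangential = -2 e^-2 < 0
        geom = None
        r = 1.0
        rho = np.array([np.exp(-2 * r)])
        # Hessian of e^(-2r): radial f'' = 4e^-2, tangential f'/r = -2e^-2
        f2, fr = 4 * np.exp(-2.0), -2 * np.exp(-2.0)
        hess = np.array([[f2], [fr], [fr], [0.0], [0.0], [0.0]])
        sr = signed_density(rho, hess)
        assert sr[0] == pytest.approx(-np.exp(-2.0))

    def test_midpoint_saddle_structure_between_separated_atoms(self):
        # two H atoms 4 A apart: the midpoint is a density saddle with one
        # positive (axial) curvature and negative tangential curvatures, so
        # lambda2 < 0 but the density there is far below the NCI rho window
        geom = MolecularGeometry(("H", "H"),
                                 np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        mid = np.array([[2.0 * BOHR_PER_ANGSTROM, 0.0, 0.0]])
        rho, _, hess = density_at(geom, mid)
        lam = eigvals3_symmetric(hess.T)
        assert lam[2][0] > 0           # axial
        assert lam[0][0] < 0 and lam[1][0] < 0   # tangential pair
        sr = signed_density(rho, hess.T)
        assert sr[0] < 0
        assert rho[0] < 0.01           # excluded from the H-bond window

    def test_zero_lambda2_maps_to_zero(self):
        hess = np.array([[1.0], [0.0], [-1.0], [0.0], [0.0], [0.0]])
        assert signed_density(np.array([0.5]), hess)[0] == 0.0


class TestScatterAndTrough:
    def test_scatter_bounded_and_sorted(self, water_dimer):
        _, field, pairs = nci_analysis(water_dimer, spacing_bohr=0.25)
        assert np.all(np.abs(pairs[:, 0]) <= 0.05)
        assert np.all(np.diff(pairs[:, 0]) >= 0)
        assert np.all(pairs[:, 1] >= 0)

    def test_empty_field_gives_empty_scatter(self):
        grid_vals = np.zeros((2, 2, 2))
        from ctclab.promolecular import DensityGrid
        grid = DensityGrid(np.zeros(3), np.ones(3), grid_vals)
        field = RDGField(rdg=np.zeros((2, 2, 2)),
                         signed_rho=np.zeros((2, 2, 2)), grid=grid)
        assert len(nci_scatter(field)) == 0

    def test_hbond_trough_present_then_vanishes_with_separation(self):
        _, _, near = nci_analysis(gen_hbond_dimer(1.9), spacing_bohr=0.2)
        _, _, far = nci_analysis(gen_hbond_dimer(4.0), spacing_bohr=0.2)
        assert hbond_trough_depth(near) < 0.6
        assert hbond_trough_depth(far) > 0.6

    def test_low_rdg_on_hbond_axis(self, water_dimer):
        # the RDG dips below 0.6 somewhere along the O...H contact axis
        h_pos = water_dimer.coords_bohr[1]
        o_pos = water_dimer.coords_bohr[3]
        ts = np.linspace(0.2, 0.8, 25)
        pts = h_pos[None, :] + ts[:, None] * (o_pos - h_pos)[None, :]
        rho, grad, _ = density_at(water_dimer, pts)
        s = compute_rdg(rho, grad.T)
        assert s.min() < 0.6


class TestCubeIO:
    def test_round_trip_grid_values(self, tmp_path, water_dimer):
        field = promolecular_density(water_dimer, spacing_bohr=0.8, margin_A=1.0)
        path = tmp_path / "rho.cube"
        export_cube(field.grid, water_dimer, path)
        grid, geom = read_cube(path)
        assert grid.shape == field.grid.shape
        np.testing.assert_allclose(grid.values, field.grid.values,
                                   rtol=1e-5, atol=1e-30)
        assert geom.elements == water_dimer.elements

    def test_header_fields(self, tmp_path, water_dimer):
        field = promolecular_density(water_dimer, spacing_bohr=1.0, margin_A=1.0)
        path = tmp_path / "rho.cube"
        export_cube(field.grid, water_dimer, path)
        lines = path.read_text().splitlines()
        assert int(lines[2].split()[0]) == water_dimer.n_atoms
        for i in (3, 4, 5):
            assert len(lines[i].split()) == 4
        assert int(lines[6].split()[0]) == 8      # oxygen Z

    def test_nonfinite_values_rejected(self, tmp_path, water_dimer):
        from ctclab.promolecular import DensityGrid
        bad = DensityGrid(np.zeros(3), np.ones(3), np.full((2, 2, 2), np.nan))
        with pytest.raises(ValueError):
            export_cube(bad, water_dimer, tmp_path / "bad.cube")

    def test_scatter_csv_round_trip(self, tmp_path):
        pairs = np.array([[-0.03, 0.2], [0.01, 1.5]])
        path = tmp_path / "scatter.csv"
        export_scatter_csv(pairs, path)
        np.testing.assert_allclose(read_scatter_csv(path), pairs, rtol=1e-6)


class TestXYZ:
    def test_round_trip(self, tmp_path, water_dimer):
        path = tmp_path / "dimer.xyz"
        write_xyz(water_dimer, path, comment="water dimer")
        back = read_xyz(path)
        assert back.elements == water_dimer.elements
        np.testing.assert_allclose(back.coords_A, water_dimer.coords_A,
                                   atol=1e-7)

    def test_close_contact_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            MolecularGeometry(("H", "H"),
                              np.array([[0.0, 0, 0], [0.3, 0, 0]]))
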