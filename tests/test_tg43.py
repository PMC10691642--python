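"""TG-43 engine: geometry function, table interpolation, superposition."""

import numpy as np
import pytest

from plaquedose import (DoseGrid, GridGeometry, SeedSource, anisotropy,
                        dose_grid_tg43, dose_rate_single,
                        geometry_factor_line, normalize_to_prescription,
                        radial_dose)
from plaquedose.grids import trilinear


def quadrature_geometry_factor(r, theta, length, n=10_000):
    """Independent oracle: numerical quadrature of 1/d^2 over the line."""
    t = (np.arange(n) + 0.5) / n * length - length / 2
    rho = r * np.sin(theta)
    z = r * np.cos(theta)
    d2 = rho**2 + (z - t) ** 2
    return np.mean(1.0 / d2)


class TestGeometryFactor:
    def test_point_source_limit(self):
        assert geometry_factor_line(1.0, np.pi / 2, 1e-9) == pytest.approx(
            1.0, rel=1e-6)

    def test_transverse_against_quadrature(self):
        val = geometry_factor_line(1.0, np.pi / 2, 0.3)
        assert val == pytest.approx(0.99258, abs=2e-5)
        assert val == pytest.approx(
            quadrature_geometry_factor(1.0, np.pi / 2, 0.3), rel=1e-6)

    @pytest.mark.parametrize("r,theta", [(0.7, 0.3), (1.3, 1.0), (2.0, 2.5),
                                         (0.4, 0.05)])
    def test_oblique_against_quadrature(self, r, theta):
        assert geometry_factor_line(r, theta, 0.3) == pytest.approx(
            quadrature_geometry_factor(r, theta, 0.3), rel=1e-5)

    def test_continuous_towards_axis(self):
        near = geometry_factor_line(1.0, 1e-7, 0.3)
        on = geometry_factor_line(1.0, 0.0, 0.3)
        assert near == pytest.approx(on, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            geometry_factor_line(0.0, 1.0, 0.3)
        with pytest.raises(ValueError):
            geometry_factor_line(0.1, 0.0, 0.3)


class TestRadialDose:
    def test_reference_radius_is_unity(self, dataset):
        assert radial_dose(1.0, dataset) == pytest.approx(1.0, abs=1e-9)

    def test_midpoint_matches_loglinear_hand_calc(self, dataset):
        r = dataset.radial_r_cm
        g = dataset.radial_g
        i = len(r) // 2
        mid = 0.5 * (r[i] + r[i + 1])
        expected = np.exp(np.log(g[i]) + (np.log(g[i + 1]) - np.log(g[i]))
                          * (mid - r[i]) / (r[i + 1] - r[i]))
        assert radial_dose(mid, dataset) == pytest.approx(expected, rel=1e-12)

    def test_monotone_beyond_buildup_and_no_exceptions(self, dataset):
        rs = np.linspace(0.05, 10.0, 400)
        vals = radial_dose(rs, dataset)  # must not raise anywhere
        assert np.all(vals > 0)
        peak = np.argmax(vals)
        tail = vals[peak:]
        assert np.all(np.diff(tail) <= 1e-12)

    def test_extrapolation_beyond_table(self, dataset):
        assert radial_dose(dataset.radial_r_cm[-1] + 1.0, dataset) \
            < dataset.radial_g[-1]


class TestAnisotropy:
    def test_transverse_axis_normalisation(self, dataset):
        assert anisotropy(1.0, np.pi / 2, dataset) == pytest.approx(1.0)

    def test_seed_ends_are_colder(self, dataset):
        assert anisotropy(1.0, 0.0, dataset) < 1.0

    def test_reproduces_table_knots(self, dataset):
        for it, t in enumerate(dataset.aniso_theta_deg):
            val = anisotropy(dataset.aniso_r_cm[0], np.radians(t), dataset)
            assert val == pytest.approx(dataset.aniso_f[0, it], rel=1e-12)

    def test_folding_above_ninety_degrees(self, dataset):
        a = anisotropy(1.0, np.radians(30.0), dataset)
        b = anisotropy(1.0, np.radians(150.0), dataset)
        assert a == pytest.approx(b, rel=1e-12)


class TestSingleSeed:
    def test_reference_position_gives_dose_rate_constant(self, dataset):
        seed = SeedSource((0, 0, 0), (0, 0, 1), 1.0)
        assert dose_rate_single(seed, (10.0, 0, 0), dataset) == \
            pytest.approx(dataset.dose_rate_constant, rel=1e-9)

    def test_strength_scaling(self, dataset):
        seed = SeedSource((0, 0, 0), (0, 0, 1), 3.15)
        assert dose_rate_single(seed, (10.0, 0, 0), dataset) == \
            pytest.approx(3.15 * dataset.dose_rate_constant, rel=1e-9)

    def test_frame_invariance_under_rotation(self, dataset, rng):
        seed = SeedSource((1.0, -2.0, 3.0), (0, 0, 1), 2.0)
        point = np.array([4.0, 1.0, -2.0])
        base = dose_rate_single(seed, point, dataset)
        # random rotation matrix
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        seed_r = SeedSource(tuple(q @ seed.position), tuple(q @ seed.axis),
                            2.0)
        assert dose_rate_single(seed_r, q @ point, dataset) == \
            pytest.approx(base, rel=1e-9)

    def test_coincident_point_rejected(self, dataset):
        seed = SeedSource((0, 0, 0), (0, 0, 1), 1.0)
        with pytest.raises(ValueError):
            dose_rate_single(seed, (0.0, 0.0, 0.0), dataset)

    def test_far_field_reduces_to_point_source(self, dataset):
        """Beyond ~5 cm the line-source dose times r^2 equals g_L * F."""
        seed = SeedSource((0, 0, 0), (0, 0, 1), 1.0)
        for r_cm in (5.0, 7.0):
            d = dose_rate_single(seed, (10 * r_cm, 0, 0), dataset)
            expected = (dataset.dose_rate_constant
                        * radial_dose(r_cm, dataset) / r_cm**2
                        / geometry_factor_line(1.0, np.pi / 2, 0.3))
            assert d == pytest.approx(expected, rel=2e-3)


class TestGridSuperposition:
    def make_seeds(self, dataset, strengths):
        return [SeedSource((x, 0.0, 0.0), (0, 0, 1), s)
                for x, s in zip((-5.0, 0.0, 5.0), strengths)]

    def test_linear_in_strength(self, dataset):
        geom = GridGeometry((-10, -10, 2), (4, 4, 4), (6, 6, 5))
        g1 = dose_grid_tg43(self.make_seeds(dataset, (1, 2, 3)), geom, dataset)
        g2 = dose_grid_tg43(self.make_seeds(dataset, (2, 4, 6)), geom, dataset)
        np.testing.assert_allclose(g2.dose, 2 * g1.dose, rtol=1e-12)

    def test_superposition_equals_per_seed_sum(self, dataset):
        geom = GridGeometry((-10, -10, 2), (4, 4, 4), (6, 6, 5))
        seeds = self.make_seeds(dataset, (1.0, 2.0, 0.5))
        total = dose_grid_tg43(seeds, geom, dataset).dose
        acc = np.zeros_like(total)
        for s in seeds:
            acc += dose_grid_tg43([s], geom, dataset).dose
        np.testing.assert_allclose(total, acc, rtol=1e-12)

    def test_mirror_symmetry_across_transverse_plane(self, dataset):
        seed = SeedSource((0, 0, 0), (0, 0, 1), 1.0)
        geom = GridGeometry((5.0, 0.0, -6.0), (1, 1, 4), (3, 1, 4))
        grid = dose_grid_tg43([seed], geom, dataset)
        np.testing.assert_allclose(grid.dose[:, :, 0], grid.dose[:, :, 3],
                                   rtol=1e-12)

    def test_thirteen_seed_loading_against_bruteforce(self, dataset, coms16):
        """Grid voxel at the prescription point equals an explicit per-seed
        loop over the same coordinates."""
        from plaquedose import assign_loading
        seeds = assign_loading(coms16, {1: 4.4, 2: 2.14, 3: 1.02})
        geom = GridGeometry((0.0, 0.0, 5.0), (1, 1, 1), (1, 1, 1))
        grid = dose_grid_tg43(seeds, geom, dataset)
        brute = sum(dose_rate_single(s, (0.0, 0.0, 5.0), dataset)
                    for s in seeds)
        assert grid.dose[0, 0, 0] == pytest.approx(brute, rel=1e-10)

    def test_rigid_rotation_invariance(self, dataset, rng):
        """Global rotation of seeds and probe points leaves doses unchanged."""
        seeds = self.make_seeds(dataset, (1.0, 0.7, 1.3))
        pts = rng.normal(scale=15.0, size=(20, 3))
        base = np.array([sum(dose_rate_single(s, p, dataset) for s in seeds)
                         for p in pts])
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        seeds_r = [SeedSource(tuple(q @ s.position), tuple(q @ s.axis),
                              s.strength) for s in seeds]
        rot = np.array([sum(dose_rate_single(s, q @ p, dataset)
                            for s in seeds_r) for p in pts])
        np.testing.assert_allclose(rot, base, rtol=1e-9)


class TestNormalization:
    def test_identity_and_doubling(self, dataset):
        geom = GridGeometry((-1, -1, -1), (1, 1, 1), (3, 3, 3))
        grid = DoseGrid(geom, np.full((3, 3, 3), 85.0),
                        metadata={"engine": "tg43"})
        out, scale = normalize_to_prescription(grid, (0, 0, 0), 85.0)
        assert scale == pytest.approx(1.0)
        grid2 = DoseGrid(geom, np.full((3, 3, 3), 42.5))
        out2, scale2 = normalize_to_prescription(grid2, (0, 0, 0), 85.0)
        assert scale2 == pytest.approx(2.0)
        assert trilinear(out2.geometry, out2.dose, (0.3, -0.2, 0.1)) == \
            pytest.approx(85.0, abs=1e-9)

    def test_zero_dose_rejected(self, dataset):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (2, 2, 2))
        grid = DoseGrid(geom, np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            normalize_to_prescription(grid, (0.5, 0.5, 0.5), 85.0)
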