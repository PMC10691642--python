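"""Monte Carlo transport: emission sampling, closed-form transport oracles,
scoring statistics."""

import numpy as np
import pytest

from plaquedose import (GridGeometry, SeedSource, VoxelPhantom,
                        i125_spectrum, run_engine, sample_emissions,
                        transport)
from plaquedose.materials import get_material
from plaquedose.mc import homogeneous_radial_kerma, mean_anisotropy


def water_phantom(side_mm=40.0, voxel=1.0, density=0.998):
    geom = GridGeometry.centered((side_mm,) * 3, voxel)
    labels = np.zeros(geom.shape, dtype=np.uint8)
    dens = np.full(geom.shape, density, dtype=np.float32)
    return VoxelPhantom(geom, labels, dens)


class TestEmissionSampling:
    def test_isotropic_mean_direction(self, dataset, rng):
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 1.0)]
        _, dirs, _, w = sample_emissions(seeds, 1_000_000, "isotropic", rng)
        assert np.linalg.norm(dirs.mean(axis=0)) < 0.005
        assert np.all(w == 1.0)

    def test_strength_apportionment(self, dataset, rng):
        seeds = [SeedSource((-10, 0, 0), (0, 0, 1), 2.0),
                 SeedSource((10, 0, 0), (0, 0, 1), 1.0)]
        pos, _, _, _ = sample_emissions(seeds, 90_000, "isotropic", rng)
        n_left = np.sum(pos[:, 0] < 0)
        # multinomial 3-sigma band around 2/3
        p = 2 / 3
        sd = np.sqrt(p * (1 - p) * 90_000)
        assert abs(n_left - p * 90_000) < 3 * sd

    def test_energy_histogram_matches_spectrum(self, dataset, rng):
        sp = i125_spectrum()
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 1.0)]
        n = 200_000
        _, _, e, _ = sample_emissions(seeds, n, "isotropic", rng)
        for line, prob in zip(sp.energies_kev, sp.probabilities):
            count = np.sum(np.isclose(e, line))
            sd = np.sqrt(n * prob * (1 - prob))
            assert abs(count - n * prob) < 3 * sd

    def test_anisotropy_weights_unbiased(self, dataset, rng):
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 1.0)]
        _, dirs, _, w = sample_emissions(seeds, 400_000,
                                         "anisotropy_weighted", rng,
                                         dataset=dataset)
        assert w.mean() == pytest.approx(1.0, abs=0.01)
        # transverse directions carry the largest weight
        cos_axis = np.abs(dirs[:, 2])
        assert w[cos_axis < 0.1].mean() > w[cos_axis > 0.9].mean()

    def test_zero_strength_rejected(self, dataset, rng):
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 0.0)]
        with pytest.raises(ValueError):
            sample_emissions(seeds, 10, "isotropic", rng)


class TestTransportOracles:
    def test_vacuum_inverse_square(self, dataset):
        """With vanishing density the scored kerma falls off as 1/r^2."""
        phantom = water_phantom(60.0, 1.0, density=1e-6)
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 1.0)]
        grid = run_engine(phantom, seeds, "full", 400_000, 5, dataset,
                          emission="isotropic", batches=4)
        xs, ys, zs = grid.geometry.voxel_centers()
        r = np.sqrt(xs**2 + ys**2 + zs**2)
        vals = []
        for r0 in (6.0, 12.0, 24.0):
            sel = (np.abs(r - r0) < 0.5)
            vals.append(np.mean(grid.dose[sel] * r[sel] ** 2))
        assert max(vals) / min(vals) < 1.05

    def test_primary_only_attenuated_point_kernel(self):
        """Scatter disabled, uniform water: kerma density equals the
        closed-form attenuated inverse-square kernel for the line spectrum."""
        water = get_material("water")
        sp = i125_spectrum()
        edges = np.array([4.75, 5.25, 9.75, 10.25, 19.5, 20.5])
        kerma = homogeneous_radial_kerma(
            "water", edges, 400_000, seed=99, half_length_mm=1e-6,
            max_scatters=0)
        for bin_idx, (r1, r2) in ((0, (4.75, 5.25)), (2, (9.75, 10.25)),
                                  (4, (19.5, 20.5))):
            rr = np.linspace(r1 / 10, r2 / 10, 200)  # cm
            k = np.zeros_like(rr)
            for e, p in zip(sp.energies_kev, sp.probabilities):
                mu = water.mu_at(e) * water.density
                k += p * e * water.mu_en_at(e) * np.exp(-mu * rr) \
                    / (4 * np.pi * rr**2)
            expected = np.sum(k * rr**2) / np.sum(rr**2)  # volume average
            assert kerma[bin_idx] == pytest.approx(expected, rel=0.03)

    def test_water_slab_beer_lambert(self):
        """Primary-only pencil beam through water follows exp(-mu z)."""
        phantom = water_phantom(30.0, 1.0)
        n = 200_000
        batch = (np.tile([0.0, 0.0, -14.0], (n, 1)),
                 np.tile([0.0, 0.0, 1.0], (n, 1)),
                 np.full(n, 28.0), np.ones(n))
        tally = transport(batch, phantom.labels, phantom.density,
                          phantom.geometry, max_scatters=0, seed=12)
        prof = tally[15, 15, :]
        z = phantom.geometry.axis_coords(2)
        water = get_material("water")
        mu = water.mu_at(28.0) * water.density
        expected = prof[1] * np.exp(-mu * (z - z[1]) / 10.0)
        np.testing.assert_allclose(prof[2:25], expected[2:25], rtol=0.03)

    def test_modulay_slab_blocks_beam(self):
        """A 0.5 mm gold-alloy slab transmits < 1e-6 of a 28 keV beam."""
        from plaquedose.materials import MATERIAL_INDEX
        phantom = water_phantom(30.0, 0.5, density=1e-6)
        labels = phantom.labels.copy()
        labels[:, :, 30:31] = MATERIAL_INDEX["modulay"]
        density = phantom.density.copy()
        density[:, :, 30:31] = 15.8
        n = 100_000
        batch = (np.tile([0.0, 0.0, -14.0], (n, 1)),
                 np.tile([0.0, 0.0, 1.0], (n, 1)),
                 np.full(n, 28.0), np.ones(n))
        blocked = transport(batch, labels, density, phantom.geometry,
                            max_scatters=0, seed=13)
        open_ = transport(batch, phantom.labels, phantom.density,
                          phantom.geometry, max_scatters=0, seed=13)
        behind = np.s_[:, :, 40:]
        assert blocked[behind].sum() < 1e-6 * open_[behind].sum()


class TestScoring:
    def test_empty_batch_gives_zero_grid(self):
        phantom = water_phantom(20.0, 2.0)
        batch = (np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0),
                 np.zeros(0))
        tally = transport(batch, phantom.labels, phantom.density,
                          phantom.geometry, seed=1)
        assert np.all(tally == 0)

    def test_history_scaling_and_uncertainty(self, dataset):
        phantom = water_phantom(40.0, 2.0)
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 1.0)]
        g1 = run_engine(phantom, seeds, "full", 100_000, 21, dataset,
                        batches=10)
        g2 = run_engine(phantom, seeds, "full", 200_000, 22, dataset,
                        batches=10)
        p = (0.0, 0.0, 8.0)
        d1, u1 = g1.probe(p, with_uncertainty=True)
        d2, u2 = g2.probe(p, with_uncertainty=True)
        # per-history dose estimate unchanged within combined uncertainty
        assert abs(d1 - d2) < 3 * np.hypot(u1 * d1, u2 * d2)
        sel = g1.dose > 0
        ratio = np.mean(g2.uncertainty[sel]) / np.mean(g1.uncertainty[sel])
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.2)

    def test_energy_bookkeeping(self, dataset):
        """Total kerma-weighted energy scored stays below emitted energy."""
        phantom = water_phantom(60.0, 2.0)
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 1.0)]
        rng = np.random.default_rng(3)
        n = 50_000
        batch = sample_emissions(seeds, n, "isotropic", rng)
        tally = transport(batch, phantom.labels, phantom.density,
                          phantom.geometry, seed=31)
        scored_kev = float((tally * phantom.density).sum())
        emitted_kev = float((batch[2] * batch[3]).sum())
        assert scored_kev <= emitted_kev * 1.01
        assert scored_kev > 0.2 * emitted_kev

    def test_spherical_symmetry_of_scoring(self, dataset):
        phantom = water_phantom(40.0, 1.0)
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 1.0)]
        grid = run_engine(phantom, seeds, "full", 400_000, 41, dataset,
                          emission="isotropic", batches=4)
        xs, ys, zs = grid.geometry.voxel_centers()
        r = np.sqrt(xs**2 + ys**2 + zs**2)
        shell = np.abs(r - 8.0) < 0.5
        up = shell & (xs > 4)
        down = shell & (xs < -4)
        a, b = grid.dose[up].mean(), grid.dose[down].mean()
        assert a == pytest.approx(b, rel=0.05)


class TestRunEngine:
    def test_mode_validation(self, dataset):
        phantom = water_phantom(20.0, 2.0)
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 1.0)]
        with pytest.raises(ValueError):
            run_engine(phantom, seeds, "bogus", 10_000, 1, dataset)

    def test_water_override_equivalence(self, dataset):
        """Full mode on an all-water phantom is the tg43_water calculation."""
        phantom = water_phantom(30.0, 2.0)
        seeds = [SeedSource((0, 0, 0), (0, 0, 1), 1.0)]
        a = run_engine(phantom, seeds, "full", 50_000, 7, dataset, batches=5)
        b = run_engine(phantom, seeds, "tg43_water", 50_000, 7, dataset,
                       batches=5)
        np.testing.assert_allclose(a.dose, b.dose, rtol=1e-12)

    def test_metadata_provenance(self, water16):
        md = water16.metadata
        assert md["engine"] == "mc"
        assert md["mode"] == "tg43_water"
        assert md["histories"] > 0
        assert "rng_seed" in md and "traversal" in md

    def test_mean_anisotropy_below_unity(self, dataset):
        phi = mean_anisotropy(dataset)
        assert 0.8 < phi < 1.0
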