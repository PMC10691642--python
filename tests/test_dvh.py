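"""Planning surface: point probes, matching criterion, loading search, DVH."""

import numpy as np
import pytest

from plaquedose import (DoseGrid, GridGeometry, PlanDefinition,
                        check_matching, compute_cdvh, dose_metric,
                        evaluate_comparison, match_loading, point_dose)
from plaquedose.dvh import ComparisonReport
from plaquedose.pipeline import TABLE1_LOADINGS


def make_grid(values, spacing=1.0, origin=(0, 0, 0), meta=None):
    values = np.asarray(values, dtype=float)
    geom = GridGeometry(origin, (spacing,) * 3, values.shape)
    return DoseGrid(geom, values, metadata=meta or {})


class TestPointDose:
    def test_constant_grid(self):
        grid = make_grid(np.full((4, 4, 4), 7.5))
        d, _ = point_dose(grid, (1.3, 2.1, 0.7))
        assert d == pytest.approx(7.5)

    def test_voxel_center_exact(self):
        vals = np.arange(27).reshape(3, 3, 3).astype(float)
        grid = make_grid(vals)
        d, _ = point_dose(grid, (1.0, 2.0, 1.0))
        assert d == pytest.approx(vals[1, 2, 1])

    def test_linear_ramp_exact(self):
        """Trilinear interpolation reproduces an affine field exactly."""
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (5, 5, 5))
        xs, ys, zs = geom.voxel_centers()
        grid = DoseGrid(geom, 2.0 * xs + 3.0 * ys - zs + 10.0)
        for p in [(1.7, 2.2, 0.9), (0.1, 3.9, 3.3), (2.5, 2.5, 2.5)]:
            d, _ = point_dose(grid, p)
            assert d == pytest.approx(2 * p[0] + 3 * p[1] - p[2] + 10,
                                      abs=1e-12)

    def test_outside_grid_rejected(self):
        grid = make_grid(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            point_dose(grid, (10.0, 0.0, 0.0))


class TestComparisonAndMatching:
    def plan(self):
        return PlanDefinition("coms16", {1: 1.0, 2: 1.0, 3: 1.0},
                              (1.0, 1.0, 1.0), 85.0,
                              comparison_point=(3.0, 1.0, 1.0))

    def test_percentage_scale_invariance(self):
        vals = np.ones((5, 5, 5)) * 85.0
        vals[3, 1, 1] = 80.0
        grid = make_grid(vals, meta={"prescription_gy": 85.0,
                                     "engine": "tg43"})
        rep1 = evaluate_comparison(self.plan(), grid)
        rep2 = evaluate_comparison(self.plan(), grid.scaled(3.7))
        assert rep1.comparison_percent == pytest.approx(
            rep2.comparison_percent, rel=1e-12)

    def test_unnormalised_grid_rejected(self):
        grid = make_grid(np.ones((5, 5, 5)))
        with pytest.raises(ValueError):
            evaluate_comparison(self.plan(), grid)

    @pytest.mark.parametrize("dose,ok", [
        (85.0, True), (80.75, True), (89.25, True), (89.26, False),
        (80.74, False)])
    def test_five_percent_criterion_boundaries(self, dose, ok):
        rep = ComparisonReport(85.0, 85.0, dose, 100 * dose / 85, 100.0,
                               "tg43")
        assert check_matching(rep) is ok


class TestMatchLoading:
    def test_single_candidate_returned(self, coms16, dataset):
        plan = PlanDefinition.preset("coms16",
                                     TABLE1_LOADINGS[("coms16", "uniform")])
        loading, scale, dev, passed = match_loading(
            coms16, [3.15], plan, dataset)
        assert set(loading.values()) == {3.15}
        assert passed and dev < 0.05

    def test_clinical_strength_set_passes(self, coms16, dataset):
        """The available clinical strengths admit an assignment matching
        both planning points within 5%."""
        plan = PlanDefinition.preset(
            "coms16", TABLE1_LOADINGS[("coms16", "nonuniform")])
        loading, scale, dev, passed = match_loading(
            coms16, [4.4, 2.14, 1.02], plan, dataset)
        assert passed

    def test_enlarging_set_never_worse(self, coms16, dataset):
        plan = PlanDefinition.preset("coms16",
                                     TABLE1_LOADINGS[("coms16", "uniform")])
        _, _, dev_small, _ = match_loading(coms16, [2.0], plan, dataset)
        _, _, dev_large, _ = match_loading(coms16, [2.0, 3.0, 1.0], plan,
                                           dataset)
        assert dev_large <= dev_small + 1e-12


class TestCDVH:
    def test_uniform_structure_step(self):
        grid = make_grid(np.full((4, 4, 4), 10.0), meta={"engine": "x"})
        mask = np.ones((4, 4, 4), dtype=bool)
        curve = compute_cdvh(grid, mask)
        assert curve.volume_fraction[0] == 1.0
        assert dose_metric(curve, 95.0) == pytest.approx(10.0, abs=0.5)
        assert dose_metric(curve, 1.0) == pytest.approx(10.0, abs=0.5)

    def test_two_voxel_structure(self):
        vals = np.zeros((2, 1, 1))
        vals[0] = 10.0
        vals[1] = 20.0
        grid = make_grid(vals)
        curve = compute_cdvh(grid, np.ones((2, 1, 1), bool))
        for edge, frac in [(0.0, 1.0), (10.0, 1.0), (10.5, 0.5),
                           (20.0, 0.5)]:
            i = int(np.searchsorted(curve.bin_edges_gy, edge))
            assert curve.volume_fraction[i] == pytest.approx(frac)

    def test_against_bruteforce_counting(self, rng):
        doses = rng.gamma(2.0, 20.0, size=(10, 10, 10))
        grid = make_grid(doses)
        mask = rng.random((10, 10, 10)) < 0.7
        curve = compute_cdvh(grid, mask, bin_width_gy=0.5)
        flat = doses[mask]
        for i, edge in enumerate(curve.bin_edges_gy):
            assert curve.volume_fraction[i] == pytest.approx(
                np.mean(flat >= edge))

    def test_empty_mask_rejected(self):
        grid = make_grid(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            compute_cdvh(grid, np.zeros((3, 3, 3), bool))


class TestDoseMetric:
    def test_ordered_doses_d95(self):
        """100 voxels with doses 1..100 Gy: D95 = 6 by the >=-convention."""
        vals = np.arange(1.0, 101.0).reshape(100, 1, 1)
        grid = make_grid(vals)
        curve = compute_cdvh(grid, np.ones((100, 1, 1), bool),
                             bin_width_gy=0.5)
        assert dose_metric(curve, 95.0) == pytest.approx(6.0, abs=1e-9)
        assert dose_metric(curve, 1.0) == pytest.approx(100.0, abs=0.5)

    def test_monotone_in_percentage(self, rng):
        vals = rng.random((8, 8, 8)) * 50
        curve = compute_cdvh(make_grid(vals), np.ones((8, 8, 8), bool))
        xs = [1, 5, 20, 50, 80, 95, 100]
        ds = [dose_metric(curve, x) for x in xs]
        assert all(a >= b - 1e-12 for a, b in zip(ds, ds[1:]))

    def test_domain(self):
        curve = compute_cdvh(make_grid(np.ones((2, 2, 2))),
                             np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError):
            dose_metric(curve, 0.0)
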