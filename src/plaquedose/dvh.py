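"""Planning surface: prescription points, comparison points, the 5% matching
criterion, loading search, and cumulative DVH metrics.

The clinical workflow mirrored here prescribes 85 Gy at the tumor apex on
the plaque central axis and verifies non-uniform loadings at a "peripheral
comparison" point on the inner sclera (the intersection of the prescription
isodose of the matched uniform plan with the sclera); both points must lie
within +/- 5% of the prescription.  Comparison-point doses are reported as a
percentage of the TG-43 dose at the central-axis prescription point.

D_x% follows the >=-convention: the largest dose received by at least x% of
the structure volume (D95% a near-minimum, D1% a near-maximum).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import DoseGrid, trilinear
from .plaque import PlaqueModel, assign_loading
from .tg43 import TG43Dataset, dose_rate_single

logger = logging.getLogger(__name__)

DEFAULT_PRESCRIPTION_GY = 85.0
MATCH_TOLERANCE = 0.05
COMPARISON_POINTS_MM = {  # published planning geometry per preset
    "coms16": (7.7, 0.0, 3.0),
    "notched20": (9.5, 0.0, 5.1),
}
PRESCRIPTION_POINTS_MM = {
    "coms16": (0.0, 0.0, 5.0),
    "notched20": (0.0, 0.0, 5.1),
}


@dataclass(frozen=True)
class PlanDefinition:
    plaque_preset: str                      # "coms16" | "notched20"
    loading: dict[int, float]               # group id -> strength (U)
    prescription_point: tuple[float, float, float]
    prescription_gy: float = DEFAULT_PRESCRIPTION_GY
    comparison_point: tuple[float, float, float] | None = None
    phantom_case: str = "water"

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription dose must be positive")

    @classmethod
    def preset(cls, name: str, loading: dict[int, float],
               phantom_case: str = "water") -> "PlanDefinition":
        return cls(name, dict(loading), PRESCRIPTION_POINTS_MM[name],
                   comparison_point=COMPARISON_POINTS_MM[name],
                   phantom_case=phantom_case)


@dataclass
class DVHCurve:
    structure: str
    engine: str
    bin_edges_gy: np.ndarray
    volume_fraction: np.ndarray   # fraction receiving >= each edge

    def __post_init__(self) -> None:
        if abs(self.volume_fraction[0] - 1.0) > 1e-12:
            raise ValueError("cDVH must start at 1.0 at zero dose")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cDVH must be non-increasing")


@dataclass
class ComparisonReport:
    prescription_gy: float
    prescription_dose_gy: float
    comparison_dose_gy: float
    comparison_percent: float          # of the TG43 CAX prescription dose
    prescription_percent: float
    engine: str
    uncertainties: dict = field(default_factory=dict)
    matched: bool | None = None


def point_dose(grid: DoseGrid, point_mm):
    """Trilinear dose probe; returns (dose, relative uncertainty)."""
    d = trilinear(grid.geometry, grid.dose, point_mm)
    u = trilinear(grid.geometry, grid.uncertainty, point_mm)
    return d, u


def evaluate_comparison(plan: PlanDefinition, grid: DoseGrid,
                        tg43_prescription_gy: float | None = None
                        ) -> ComparisonReport:
    """Point-dose report in the published Table-3 convention.

    The grid must be normalised (carry ``prescription_gy`` metadata).  For a
    TG-43 grid the denominator is its own prescription-point dose; for an MC
    grid pass ``tg43_prescription_gy`` (the TG-43 value under the shared
    normalisation) explicitly.
    """
    if "prescription_gy" not in grid.metadata:
        raise ValueError("grid is not normalised to a prescription")
    if plan.comparison_point is None:
        raise ValueError("plan has no comparison point")
    d_pre, u_pre = point_dose(grid, plan.prescription_point)
    d_cmp, u_cmp = point_dose(grid, plan.comparison_point)
    ref = tg43_prescription_gy if tg43_prescription_gy is not None else d_pre
    return ComparisonReport(
        prescription_gy=plan.prescription_gy,
        prescription_dose_gy=d_pre,
        comparison_dose_gy=d_cmp,
        comparison_percent=100.0 * d_cmp / ref,
        prescription_percent=100.0 * d_pre / ref,
        engine=str(grid.metadata.get("engine", "unknown")),
        uncertainties={"prescription": u_pre, "comparison": u_cmp})


def check_matching(report: ComparisonReport,
                   tolerance: float = MATCH_TOLERANCE) -> bool:
    """Both points within +/- tolerance of the prescription (inclusive)."""
    rx = report.prescription_gy
    ok = (abs(report.prescription_dose_gy - rx) <= tolerance * rx + 1e-12
          and abs(report.comparison_dose_gy - rx) <= tolerance * rx + 1e-12)
    report.matched = ok
    return ok


def match_loading(model: PlaqueModel, available_strengths, plan: PlanDefinition,
                  dataset: TG43Dataset, tolerance: float = MATCH_TOLERANCE):
    """Exhaustive group-wise assignment search over an available strength set.

    Each candidate assignment enjoys a global scale freedom (implant-time /
    renormalisation): the scale minimising the worse of the two point
    deviations is applied before judging.  Returns
    ``(loading dict, scale, max relative deviation, passed)`` with a
    deterministic lexicographic tie-break.
    """
    strengths = sorted(set(float(s) for s in available_strengths))
    if not strengths:
        raise ValueError("empty strength set")
    groups = sorted(model.groups)
    if len(groups) > 3:
        raise ValueError("search supports at most 3 groups")
    # per-group unit response at the two points
    unit = np.zeros((len(groups), 2))
    for gi, g in enumerate(groups):
        seeds = assign_loading(model, {gg: (1.0 if gg == g else 0.0)
                                       for gg in groups})
        for pi, pt in enumerate((plan.prescription_point,
                                 plan.comparison_point)):
            unit[gi, pi] = sum(dose_rate_single(s, pt, dataset)
                               for s in seeds if s.strength > 0)
    best = None
    for combo in itertools.product(strengths, repeat=len(groups)):
        w = np.asarray(combo)
        d1, d2 = w @ unit
        if d1 <= 0 or d2 <= 0:
            continue
        rx = plan.prescription_gy
        scale = 2 * rx / (d1 + d2)  # minimax over the two points
        dev = max(abs(scale * d1 - rx), abs(scale * d2 - rx)) / rx
        key = (dev, combo)
        if best is None or key < best[0]:
            best = (key, dict(zip(groups, combo)), scale, dev)
    _, loading, scale, dev = best
    passed = dev <= tolerance
    if not passed:
        logger.warning("no assignment meets the %.0f%% criterion; best "
                       "deviation %.1f%%", 100 * tolerance, 100 * dev)
    return loading, scale, dev, passed


def compute_cdvh(grid: DoseGrid, mask: np.ndarray,
                 bin_width_gy: float = 0.5, structure: str = "",
                 ) -> DVHCurve:
    """Cumulative DVH: fraction of masked volume receiving >= each bin edge.

    Voxels of a regular grid share one volume, so the fraction is a plain
    count ratio.
    """
    if mask.dtype != bool or mask.shape != grid.dose.shape:
        raise ValueError("mask must be a boolean grid matching the dose")
    doses = grid.dose[mask]
    if doses.size == 0:
        raise ValueError("empty structure mask")
    top = float(doses.max())
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    frac = np.array([(doses >= e).mean() for e in edges])
    return DVHCurve(structure, str(grid.metadata.get("engine", "")),
                    edges, frac)


def dose_metric(curve: DVHCurve, x_percent: float) -> float:
    """D_x%: largest dose with cumulative volume fraction >= x/100
    (linear interpolation between bin edges)."""
    if not 0 < x_percent <= 100:
        raise ValueError("x must be in (0, 100]")
    target = x_percent / 100.0
    v = curve.volume_fraction
    e = curve.bin_edges_gy
    if v[-1] >= target:
        return float(e[-1])
    idx = int(np.argmax(v < target))  # first edge below target
    if idx == 0:
        return 0.0
    v1, v2 = v[idx - 1], v[idx]
    if v1 == v2:
        return float(e[idx - 1])
    t = (v1 - target) / (v1 - v2)
    return float(e[idx - 1] + t * (e[idx] - e[idx - 1]))


def dx_table(grid: DoseGrid, structures: dict[str, np.ndarray],
             percentages=(1.0, 20.0, 95.0), bin_width_gy: float = 0.5,
             exclude: np.ndarray | None = None) -> dict[str, dict[float, float]]:
    """D_x% for each structure; optionally excluding a region (notch cut)."""
    out: dict[str, dict[float, float]] = {}
    for name, mask in structures.items():
        m = mask & ~exclude if exclude is not None else mask
        if not m.any():
            continue
        curve = compute_cdvh(grid, m, bin_width_gy, structure=name)
        out[name] = {p: dose_metric(curve, p) for p in percentages}
    return out
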