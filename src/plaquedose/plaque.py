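"""COMS-style eye-plaque geometry: gold-alloy (modulay) shell, silastic seed
carrier, optional cylindrical notch, and seed-slot layouts.

Coordinate convention (shared package-wide): the plaque central axis is +z
pointing into the eye, the concave silastic apex touches the outer sclera at
(0, 0, -1) mm, so the inner sclera surface crosses the axis at z = 0 and the
prescription point sits at (0, 0, 5) mm.  The common centre of curvature of
plaque and globe is at (0, 0, roc - 1).

The "plaque radius" of 12.3 mm is the radius of curvature of the concave
surface (the COMS engineering reading); the nominal diameter (16/20 mm) is
the chord diameter of the concave footprint on the globe, which fixes the
cap half-angle.  Seed slots lie on rings of the sphere 1 mm above the
concave surface with seed long axes tangent to the ring (the COMS
convention); the shipped slot tables are CSV resources under ``data/``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .grids import GridGeometry
from .materials import MATERIAL_INDEX
from .tg43 import SeedSource

logger = logging.getLogger(__name__)

SEED_LENGTH_MM = 4.5        # physical seed envelope
SEED_RADIUS_MM = 0.4
SEED_DEPTH_MM = 1.0         # seed-centre height above the concave surface

M_EXTERIOR = "exterior"
M_SILASTIC = "silastic"
M_MODULAY = "modulay"


@dataclass(frozen=True)
class NotchSpec:
    radius: float = 4.0          # mm, cylindrical cut-out
    center_offset: float = 9.0   # mm along -x from the plaque centre
    wall_thickness: float = 0.5  # mm, equals the modulay thickness

    def __post_init__(self) -> None:
        if min(self.radius, self.center_offset, self.wall_thickness) <= 0:
            raise ValueError("notch dimensions must be positive")


@dataclass(frozen=True)
class PlaqueSpec:
    nominal_diameter: float
    radius_of_curvature: float = 12.3
    modulay_thickness: float = 0.5
    silastic_thickness: float = 2.25
    lip_thickness: float = 0.5  # gold rim band covering the silastic edge
    notch: NotchSpec | None = None

    def __post_init__(self) -> None:
        if min(self.modulay_thickness, self.silastic_thickness,
               self.radius_of_curvature, self.nominal_diameter) <= 0:
            raise ValueError("plaque dimensions must be positive")
        if self.lip_thickness < 0:
            raise ValueError("lip thickness cannot be negative")

    @property
    def sphere_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.radius_of_curvature - 1.0])

    @property
    def cap_half_angle(self) -> float:
        s = (self.nominal_diameter / 2.0) / self.radius_of_curvature
        if s >= 1:
            raise ValueError("nominal diameter exceeds the shell diameter")
        return math.asin(s)


@dataclass(frozen=True)
class SeedSlot:
    group_id: int
    position: tuple[float, float, float]
    axis: tuple[float, float, float]


@dataclass(frozen=True)
class PlaqueModel:
    spec: PlaqueSpec
    slots: tuple[SeedSlot, ...]

    @property
    def groups(self) -> set[int]:
        return {s.group_id for s in self.slots}

    def material_at(self, points_mm) -> np.ndarray:
        """Material label for each query point: exterior/silastic/modulay.

        Boundary points belong to the denser material.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        spec = self.spec
        v = pts - spec.sphere_center
        r = np.linalg.norm(v, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_psi = np.where(r > 0, -v[:, 2] / np.maximum(r, 1e-300), 1.0)
        in_cap = cos_psi >= math.cos(spec.cap_half_angle) - 1e-12
        r_in = spec.radius_of_curvature
        r_mid = r_in + spec.silastic_thickness
        r_out = r_mid + spec.modulay_thickness
        silastic = in_cap & (r >= r_in) & (r < r_mid)
        modulay = in_cap & (r >= r_mid) & (r <= r_out)
        if spec.lip_thickness > 0:
            # the gold shell curls over the silastic rim: a full-thickness
            # band of modulay just beyond the cap angle (the COMS lip)
            cos_lip = math.cos(spec.cap_half_angle
                               + spec.lip_thickness / spec.radius_of_curvature)
            lip = (~in_cap) & (cos_psi >= cos_lip - 1e-12) \
                & (r >= r_in) & (r <= r_out)
            modulay = modulay | lip
        if spec.notch is not None:
            rn = np.hypot(pts[:, 0] + spec.notch.center_offset, pts[:, 1])
            in_shell = silastic | modulay
            cut = in_shell & (rn < spec.notch.radius)
            wall = in_shell & ~cut & (rn <= spec.notch.radius
                                      + spec.notch.wall_thickness)
            silastic = silastic & ~cut & ~wall
            modulay = (modulay & ~cut) | wall
        out = np.full(pts.shape[0], M_EXTERIOR, dtype=object)
        out[silastic] = M_SILASTIC
        out[modulay] = M_MODULAY
        if np.asarray(points_mm).ndim == 1:
            return out[0]
        return out

    def shell_volume_mm3(self) -> float:
        """Analytic modulay volume: spherical-cap backing shell plus the
        full-thickness rim lip band (the notch is ignored)."""
        spec = self.spec
        a = spec.cap_half_angle
        r0 = spec.radius_of_curvature
        r1 = r0 + spec.silastic_thickness
        r2 = r1 + spec.modulay_thickness
        back = 2 * math.pi * (1 - math.cos(a)) / 3 * (r2**3 - r1**3)
        a_lip = a + spec.lip_thickness / r0
        lip = 2 * math.pi * (math.cos(a) - math.cos(a_lip)) / 3 \
            * (r2**3 - r0**3)
        return back + lip


def _load_slots(diameter: int) -> tuple[SeedSlot, ...]:
    data = resources.files("plaquedose.data")
    table = np.loadtxt(data / f"coms_slots_{diameter}.csv",
                       delimiter=",", skiprows=1, ndmin=2)
    slots = []
    for row in table:
        axis = row[4:7] / np.linalg.norm(row[4:7])
        slots.append(SeedSlot(int(row[0]), tuple(row[1:4]), tuple(axis)))
    return tuple(slots)


def build_coms_plaque(diameter: float) -> PlaqueModel:
    """Standard COMS plaque preset (16 or 20 mm)."""
    if int(diameter) not in (16, 20):
        raise ValueError("supported presets: 16, 20 (mm nominal diameter)")
    spec = PlaqueSpec(nominal_diameter=float(diameter))
    model = PlaqueModel(spec, _load_slots(int(diameter)))
    _check_slots(model)
    return model


def build_notched_plaque(spec: PlaqueSpec | None = None) -> PlaqueModel:
    """20 mm COMS plaque with the cylindrical notch; intersected slots removed."""
    if spec is None:
        spec = PlaqueSpec(nominal_diameter=20.0, notch=NotchSpec())
    if spec.notch is None:
        raise ValueError("notched plaque requires a NotchSpec")
    rim = spec.nominal_diameter / 2.0
    if spec.notch.center_offset - spec.notch.radius >= rim:
        raise ValueError("notch does not intersect the plaque rim")
    base = _load_slots(int(spec.nominal_diameter))
    kept = tuple(s for s in base if not _slot_hits_notch(s, spec.notch))
    model = PlaqueModel(spec, kept)
    _check_slots(model)
    return model


def _slot_hits_notch(slot: SeedSlot, notch: NotchSpec) -> bool:
    """A slot is removed when its seed envelope intersects the cut dilated by
    the wall thickness (a physical seed cannot occupy the cut)."""
    pos = np.asarray(slot.position)
    axis = np.asarray(slot.axis)
    t = np.linspace(-SEED_LENGTH_MM / 2, SEED_LENGTH_MM / 2, 31)
    pts = pos[None, :] + t[:, None] * axis[None, :]
    rn = np.hypot(pts[:, 0] + notch.center_offset, pts[:, 1])
    return bool(np.min(rn) - SEED_RADIUS_MM
                < notch.radius + notch.wall_thickness)


def _check_slots(model: PlaqueModel) -> None:
    if not model.slots:
        raise ValueError("plaque has no seed slots")
    pts = np.array([s.position for s in model.slots])
    mats = model.material_at(pts)
    if np.any(mats != M_SILASTIC):
        bad = [i for i, m in enumerate(mats) if m != M_SILASTIC]
        raise ValueError(f"slot centres outside silastic: {bad}")


def assign_loading(model: PlaqueModel, strengths: dict[int, float]):
    """One SeedSource per slot with its group's air-kerma strength (U)."""
    missing = model.groups - set(strengths)
    if missing:
        raise KeyError(f"no strength given for group(s) {sorted(missing)}")
    return [SeedSource(s.position, s.axis, float(strengths[s.group_id]))
            for s in model.slots]


def uniform_loading(model: PlaqueModel, strength: float):
    return assign_loading(model, {g: strength for g in model.groups})


def voxelize(model: PlaqueModel, geometry: GridGeometry, subsample: int = 2):
    """Rasterise the plaque onto a grid by sub-voxel occupancy sampling.

    Returns ``(labels, occupancy)``: ``labels`` is a uint8 grid using the
    package material ids (0 = exterior/water) assigning each voxel its
    majority material with ties broken toward the denser one; ``occupancy``
    maps material name -> fractional volume grid (float32).  Only the plaque
    bounding box is visited.
    """
    spec = model.spec
    if max(geometry.spacing) > spec.modulay_thickness:
        logger.warning("voxel size %.2f mm exceeds modulay thickness; the "
                       "shell may be undersampled", max(geometry.spacing))
    r_out = spec.radius_of_curvature + spec.silastic_thickness \
        + spec.modulay_thickness
    c = spec.sphere_center
    lo = c - r_out
    hi = c + r_out
    a_eff = spec.cap_half_angle + spec.lip_thickness / spec.radius_of_curvature
    hi[2] = c[2] - spec.radius_of_curvature * math.cos(a_eff) \
        + 1.5  # cap (+ lip) only occupies the lower part of the sphere
    occ = {M_SILASTIC: np.zeros(geometry.shape, dtype=np.float32),
           M_MODULAY: np.zeros(geometry.shape, dtype=np.float32)}
    spacing = np.asarray(geometry.spacing)
    origin = np.asarray(geometry.origin)
    idx_lo = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    idx_hi = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1,
                        np.asarray(geometry.shape))
    if np.any(idx_lo >= idx_hi):
        labels = np.zeros(geometry.shape, dtype=np.uint8)
        return labels, occ
    sub = (np.arange(subsample) + 0.5) / subsample - 0.5
    offsets = np.stack(np.meshgrid(sub, sub, sub, indexing="ij"),
                       axis=-1).reshape(-1, 3) * spacing
    ii = [np.arange(idx_lo[a], idx_hi[a]) for a in range(3)]
    xs, ys, zs = np.meshgrid(*(origin[a] + spacing[a] * ii[a]
                               for a in range(3)), indexing="ij")
    centers = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    counts = {M_SILASTIC: np.zeros(centers.shape[0]),
              M_MODULAY: np.zeros(centers.shape[0])}
    for off in offsets:
        mats = model.material_at(centers + off)
        counts[M_SILASTIC] += mats == M_SILASTIC
        counts[M_MODULAY] += mats == M_MODULAY
    n_sub = len(offsets)
    shape_box = tuple(idx_hi - idx_lo)
    sl = tuple(slice(idx_lo[a], idx_hi[a]) for a in range(3))
    for m in (M_SILASTIC, M_MODULAY):
        occ[m][sl] = (counts[m] / n_sub).reshape(shape_box).astype(np.float32)
    labels = np.zeros(geometry.shape, dtype=np.uint8)
    f_sil = occ[M_SILASTIC]
    f_mod = occ[M_MODULAY]
    majority_sil = (f_sil > 0.5) & (f_sil > f_mod)
    # ties / equal shares break toward the denser modulay
    majority_mod = (f_mod >= 0.5) | ((f_mod > 0) & (f_mod + f_sil > 0.5)
                                     & (f_mod >= f_sil))
    labels[majority_sil] = MATERIAL_INDEX["silastic"]
    labels[majority_mod] = MATERIAL_INDEX["modulay"]
    return labels, occ


def describe(model: PlaqueModel) -> str:
    spec = model.spec
    lines = [
        f"nominal diameter : {spec.nominal_diameter:.1f} mm",
        f"radius of curvature: {spec.radius_of_curvature:.2f} mm",
        f"modulay / silastic thickness: {spec.modulay_thickness:.2f} / "
        f"{spec.silastic_thickness:.2f} mm",
        f"cap half-angle   : {math.degrees(spec.cap_half_angle):.1f} deg",
        f"seed slots       : {len(model.slots)}",
    ]
    if spec.notch:
        lines.append(f"notch: r={spec.notch.radius} mm at "
                     f"(-{spec.notch.center_offset}, 0) mm")
    lines.append("group  x_mm    y_mm    z_mm    axis")
    for s in model.slots:
        lines.append(f"  {s.group_id}   {s.position[0]:7.2f} {s.position[1]:7.2f} "
                     f"{s.position[2]:7.2f}  ({s.axis[0]:+.3f},{s.axis[1]:+.3f},"
                     f"{s.axis[2]:+.3f})")
    return "\n".join(lines)
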