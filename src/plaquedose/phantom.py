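"""Synthetic voxel phantoms: the 10 cm water cube and an analytic eye model.

The eye phantom emulates a CT-derived ocular model on a
0.39 x 0.39 x 0.4 mm grid: a spherical globe (outer diameter 24.6 mm) with a
1 mm sclera shell, an ellipsoidal lens, a cylindrical optic nerve (nerve +
sheath) and a dome-shaped (spherical-cap) choroidal tumor, all surrounded by
soft tissue.  Two clinical situations are provided:

* ``medial``   — tumor centred on the plaque axis, optic nerve exiting well
  away from the plaque; treated with a standard COMS plaque;
* ``juxtapapillary`` — tumor abutting the optic nerve, which runs coaxially
  with the notch of a 20 mm notched plaque (1 mm soft-tissue gap between
  nerve sheath and the modulay notch wall).

The frame is plaque-centric (see plaque.py): the plaque concave apex is at
(0, 0, -1) mm, the inner sclera crosses the axis at z = 0, and the common
centre of curvature is at (0, 0, 11.3) mm for the default globe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .grids import GridGeometry
from .materials import MATERIAL_INDEX, MATERIAL_ORDER, get_material
from .plaque import PlaqueModel, voxelize

logger = logging.getLogger(__name__)

VOXEL_MM = (0.39, 0.39, 0.4)


@dataclass
class VoxelPhantom:
    geometry: GridGeometry
    labels: np.ndarray            # uint8, MATERIAL_INDEX ids
    density: np.ndarray           # float32, g/cm^3
    structures: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.shape != self.geometry.shape:
            raise ValueError("label grid does not match geometry")
        if self.density.shape != self.labels.shape:
            raise ValueError("density grid does not match labels")
        if np.any(self.density <= 0):
            raise ValueError("densities must be positive")
        for name, mask in self.structures.items():
            if mask.shape != self.labels.shape or mask.dtype != bool:
                raise ValueError(f"bad structure mask {name!r}")


@dataclass(frozen=True)
class EyeModelConfig:
    globe_outer_diameter: float = 24.6
    sclera_thickness: float = 1.0
    lens_semi_axes: tuple[float, float, float] = (4.5, 4.5, 2.0)
    lens_depth: float = 5.5              # lens centre below the anterior pole
    nerve_diameter: float = 5.0          # optic nerve + sheath
    nerve_polar_angle_deg: float = 100.0  # medial case: angle from plaque axis
    tumor_base_diameter: float = 12.0
    tumor_apex_height: float = 5.0
    location: str = "medial"             # or "juxtapapillary"
    notch_offset: float = 9.0            # juxtapapillary nerve axis offset, -x
    voxel_mm: tuple[float, float, float] = VOXEL_MM
    extent_mm: tuple[float, float, float] = (60.0, 60.0, 50.0)

    def __post_init__(self) -> None:
        if self.tumor_apex_height >= self.globe_outer_diameter / 2:
            raise ValueError("tumor apex height exceeds the globe radius")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel sizes must be positive")
        if self.location not in ("medial", "juxtapapillary"):
            raise ValueError("location must be medial or juxtapapillary")

    @property
    def globe_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.globe_outer_diameter / 2 - 1.0])

    @property
    def outer_radius(self) -> float:
        return self.globe_outer_diameter / 2

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.sclera_thickness


def _grid_for(config: EyeModelConfig) -> GridGeometry:
    ex = np.asarray(config.extent_mm)
    sp = np.asarray(config.voxel_mm)
    shape = np.maximum(np.round(ex / sp).astype(int), 1)
    # x/y centred on the plaque axis; z from -15 mm (behind the plaque)
    origin = np.array([-(shape[0] - 1) / 2 * sp[0],
                       -(shape[1] - 1) / 2 * sp[1],
                       -15.0 + sp[2] / 2])
    return GridGeometry(tuple(origin), tuple(sp), tuple(int(n) for n in shape))


def build_water_box(side_mm: float = 100.0, voxel_mm: float = 1.0) -> VoxelPhantom:
    """Uniform water cube centred on the plaque coordinate origin."""
    if side_mm < 40:
        raise ValueError("water box smaller than 40 mm gives inadequate scatter")
    geom = GridGeometry.centered((side_mm,) * 3, voxel_mm)
    labels = np.full(geom.shape, MATERIAL_INDEX["water"], dtype=np.uint8)
    density = np.full(geom.shape, get_material("water").density,
                      dtype=np.float32)
    return VoxelPhantom(geom, labels, density,
                        metadata={"kind": "water_box", "side_mm": side_mm})


def tumor_cap_sphere(config: EyeModelConfig):
    """Centre (mm) and radius of the sphere whose cap forms the tumor dome."""
    a = config.tumor_base_diameter / 2
    h = config.tumor_apex_height
    r_cap = (a * a + h * h) / (2 * h)
    cx = 0.0
    if config.location == "juxtapapillary":
        # shift the dome toward the nerve so its rasterised base reaches the
        # optic disc (the dome-sclera intersection circle is smaller than
        # the nominal base; 1 mm compensates the curvature)
        nerve_surface_x = -(config.notch_offset - config.nerve_diameter / 2)
        cx = nerve_surface_x + a - 1.0
    center = np.array([cx, 0.0, h - r_cap])
    return center, r_cap


def tumor_dome_volume_mm3(config: EyeModelConfig) -> float:
    """Analytic tumor volume: the dome is the intersection of the cap sphere
    with the globe interior, i.e. a two-sphere lens (the base follows the
    curved inner sclera, not a plane)."""
    t_c, r1 = tumor_cap_sphere(config)
    r2 = config.inner_radius
    d = float(np.linalg.norm(t_c - config.globe_center))
    return (math.pi * (r1 + r2 - d) ** 2
            * (d * d + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2) / (12 * d))


def build_eye_phantom(config: EyeModelConfig | None = None):
    """Rasterise the analytic eye model; returns (VoxelPhantom, structures).

    Overlaps are resolved with the priority
    tumor > lens > optic nerve > sclera > vitreous > soft tissue.
    """
    config = config or EyeModelConfig()
    geom = _grid_for(config)
    xs, ys, zs = geom.voxel_centers()
    g = config.globe_center
    r2 = (xs - g[0]) ** 2 + (ys - g[1]) ** 2 + (zs - g[2]) ** 2
    r = np.sqrt(r2)
    inside_globe = r <= config.inner_radius
    sclera = (r > config.inner_radius) & (r <= config.outer_radius)

    # lens: ellipsoid on the anterior axis
    lens_c = g + np.array([0.0, 0.0,
                           config.outer_radius - config.lens_depth])
    la, lb, lc = config.lens_semi_axes
    lens = (((xs - lens_c[0]) / la) ** 2 + ((ys - lens_c[1]) / lb) ** 2
            + ((zs - lens_c[2]) / lc) ** 2) <= 1.0
    lens &= inside_globe | sclera

    # tumor dome on the inner sclera
    t_c, t_r = tumor_cap_sphere(config)
    tumor = ((xs - t_c[0]) ** 2 + (ys - t_c[1]) ** 2
             + (zs - t_c[2]) ** 2 <= t_r * t_r) & inside_globe

    # optic nerve cylinder; the nerve head pierces the sclera down to the
    # inner surface (the optic disc), so the mask starts at the inner radius
    nerve_r = config.nerve_diameter / 2
    if config.location == "juxtapapillary":
        dist = np.hypot(xs + config.notch_offset, ys)
        nerve = (dist <= nerve_r) & (r > config.inner_radius) & (zs <= g[2])
    else:
        ang = math.radians(config.nerve_polar_angle_deg)
        axis = np.array([math.sin(ang), 0.0, -math.cos(ang)])
        exit_pt = g + config.inner_radius * axis
        px = xs - exit_pt[0]
        py = ys - exit_pt[1]
        pz = zs - exit_pt[2]
        along = px * axis[0] + py * axis[1] + pz * axis[2]
        perp2 = px * px + py * py + pz * pz - along * along
        nerve = (perp2 <= nerve_r**2) & (along >= 0) \
            & (r > config.inner_radius)

    labels = np.full(geom.shape, MATERIAL_INDEX["soft_tissue"], dtype=np.uint8)
    labels[sclera] = MATERIAL_INDEX["sclera"]
    labels[inside_globe] = MATERIAL_INDEX["vitreous"]
    masks = {}
    # ascending priority so later assignments win
    for name, mask in [("exterior_tissue",
                        ~(inside_globe | sclera | nerve | lens | tumor)),
                       ("vitreous", inside_globe),
                       ("sclera", sclera),
                       ("optic_nerve", nerve),
                       ("lens", lens),
                       ("tumor", tumor)]:
        masks[name] = mask
    order = ["vitreous", "sclera", "optic_nerve", "lens", "tumor"]
    for name in order:
        mat = {"vitreous": "vitreous", "sclera": "sclera",
               "optic_nerve": "optic_nerve", "lens": "lens",
               "tumor": "tumor"}[name]
        labels[masks[name]] = MATERIAL_INDEX[mat]
    # make masks mutually exclusive by the same priority
    claimed = np.zeros(geom.shape, dtype=bool)
    for name in reversed(order):  # highest priority first
        masks[name] = masks[name] & ~claimed
        claimed |= masks[name]
    masks["exterior_tissue"] &= ~claimed
    density = np.empty(geom.shape, dtype=np.float32)
    for mat_name, mat_id in MATERIAL_INDEX.items():
        sel = labels == mat_id
        if np.any(sel):
            density[sel] = get_material(mat_name).density
    phantom = VoxelPhantom(geom, labels, density, structures=masks,
                           metadata={"kind": "eye", "location": config.location,
                                     "config": config.__dict__.copy()})
    return phantom, masks


def place_plaque(phantom: VoxelPhantom, plaque: PlaqueModel,
                 case: str = "standard", subsample: int = 2) -> VoxelPhantom:
    """Embed a plaque into the phantom's label/density grids.

    Plaque material overwrites only water / soft-tissue voxels (never sclera
    or interior structures); voxel densities are occupancy-weighted so that
    partially filled shell voxels conserve areal density.  For the notched
    case the interior of the cut is recorded as the ``notch_cut`` structure
    (the region in which the reference workflow does not score dose).
    """
    if case not in ("standard", "notched"):
        raise ValueError("case must be standard or notched")
    if (case == "notched") != (plaque.spec.notch is not None):
        raise ValueError("plaque preset does not match the requested case")
    cfg = phantom.metadata.get("config", {})
    globe_r = cfg.get("globe_outer_diameter", 24.6) / 2
    overlap = plaque.spec.radius_of_curvature - globe_r
    if overlap < -0.2:
        raise ValueError("plaque interpenetrates the globe beyond 0.2 mm")
    labels = phantom.labels.copy()
    density = phantom.density.copy()
    plq_labels, occ = voxelize(plaque, phantom.geometry, subsample=subsample)
    overwritable = np.isin(labels, [MATERIAL_INDEX["water"],
                                    MATERIAL_INDEX["soft_tissue"]])
    for mat in ("silastic", "modulay"):
        sel = (plq_labels == MATERIAL_INDEX[mat]) & overwritable
        labels[sel] = MATERIAL_INDEX[mat]
    f_sil = occ["silastic"]
    f_mod = occ["modulay"]
    blend = overwritable & ((f_sil > 0) | (f_mod > 0))
    base = density[blend] * np.maximum(1.0 - f_sil[blend] - f_mod[blend], 0.0)
    density[blend] = (base + f_sil[blend] * get_material("silastic").density
                      + f_mod[blend] * get_material("modulay").density)
    structures = dict(phantom.structures)
    if case == "notched":
        xs, ys, zs = phantom.geometry.voxel_centers()
        notch = plaque.spec.notch
        rn = np.hypot(xs + notch.center_offset, ys)
        r_out = (plaque.spec.radius_of_curvature
                 + plaque.spec.silastic_thickness
                 + plaque.spec.modulay_thickness)
        c = plaque.spec.sphere_center
        rr = np.sqrt((xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2)
        structures["notch_cut"] = ((rn < notch.radius)
                                   & (rr >= plaque.spec.radius_of_curvature)
                                   & (rr <= r_out))
    out = VoxelPhantom(phantom.geometry, labels, density, structures,
                       metadata={**phantom.metadata, "plaque":
                                 {"diameter": plaque.spec.nominal_diameter,
                                  "case": case, "n_slots": len(plaque.slots)}})
    return out
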