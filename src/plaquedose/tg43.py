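"""AAPM TG-43 2D line-source dose formalism for I-125 seeds.

The general 2D equation

    D(r, theta) = S_K * Lambda * G_L(r,theta)/G_L(r0,theta0)
                  * g_L(r) * F(r,theta)

is evaluated per seed and superposed.  ``r0 = 1 cm``, ``theta0 = 90 deg``.
Distances handed to the public API are in millimetres (converted to cm
internally), dose rates in cGy/h per U of air-kerma strength.

The packaged 6711-type dataset lives under ``data/``:
``Lambda = 0.965 cGy/(h U)``, active length 3.0 mm, a radial dose function
generated with the package's homogeneous-water Monte Carlo, and a smooth
polar anisotropy table used consistently by both this engine and the Monte
Carlo emission model (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .grids import DoseGrid, GridGeometry, trilinear

logger = logging.getLogger(__name__)

R0_CM = 1.0
THETA0 = np.pi / 2


@dataclass(frozen=True)
class SeedSource:
    """One physical seed: centre position (mm), long axis, strength in U."""

    position: tuple[float, float, float]
    axis: tuple[float, float, float]
    strength: float

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
            raise ValueError("seed axis must be a unit vector")
        if self.strength < 0:
            raise ValueError("air-kerma strength must be non-negative")


@dataclass(frozen=True)
class TG43Dataset:
    dose_rate_constant: float      # Lambda, cGy/(h U)
    active_length_cm: float        # L
    radial_r_cm: np.ndarray
    radial_g: np.ndarray
    aniso_r_cm: np.ndarray
    aniso_theta_deg: np.ndarray    # [0, 90], half-range table
    aniso_f: np.ndarray            # shape (n_r, n_theta)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.radial_r_cm) > 0):
            raise ValueError("radial table radii must be strictly increasing")
        if np.any(self.radial_g <= 0) or np.any(self.aniso_f <= 0):
            raise ValueError("table values must be positive")
        g1 = np.interp(1.0, self.radial_r_cm, self.radial_g)
        if abs(g1 - 1.0) > 1e-9:
            raise ValueError("g_L(1 cm) must equal 1")
        if np.max(np.abs(self.aniso_f[:, -1] - 1.0)) > 1e-9:
            raise ValueError("F(r, 90 deg) must equal 1")


def load_default_dataset() -> TG43Dataset:
    data = resources.files("plaquedose.data")
    radial = np.loadtxt(data / "tg43_6711_radial.csv", delimiter=",", skiprows=1)
    aniso = np.loadtxt(data / "tg43_6711_anisotropy.csv", delimiter=",", skiprows=1)
    with (data / "tg43_6711_anisotropy.csv").open() as fh:
        header = fh.readline().strip().split(",")[1:]
    r_vals = np.array([float(h) for h in header])
    return TG43Dataset(
        dose_rate_constant=0.965,
        active_length_cm=0.30,
        radial_r_cm=radial[:, 0],
        radial_g=radial[:, 1],
        aniso_r_cm=r_vals,
        aniso_theta_deg=aniso[:, 0],
        aniso_f=aniso[:, 1:].T,
    )


def geometry_factor_line(r_cm, theta_rad, length_cm) -> np.ndarray:
    """TG-43 line-source geometry function G_L(r, theta) in cm^-2.

    Off axis ``beta/(L r sin theta)`` with beta the angle subtended by the
    active line; on axis ``1/(r^2 - L^2/4)``.
    """
    r = np.asarray(r_cm, dtype=float)
    theta = np.asarray(theta_rad, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    half = length_cm / 2.0
    sin_t = np.sin(theta)
    cos_t = np.cos(theta)
    on_axis = np.abs(sin_t) < 1e-8
    if np.any(on_axis & (r <= half)):
        raise ValueError("on-axis point inside the active line")
    rho = np.where(on_axis, 1.0, r * sin_t)  # placeholder on axis
    z = r * cos_t
    beta = np.arctan2(z + half, rho) - np.arctan2(z - half, rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_off = beta / (length_cm * rho)
        g_on = 1.0 / (r**2 - half**2)
    out = np.where(on_axis, g_on, g_off)
    return out if out.ndim else float(out)


def radial_dose(r_cm, dataset: TG43Dataset) -> np.ndarray:
    """g_L(r): log-linear interpolation, log-linear extrapolation beyond ends."""
    r = np.asarray(r_cm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    rt, gt = dataset.radial_r_cm, np.log(dataset.radial_g)
    lng = np.interp(r, rt, gt)
    # log-linear extrapolation from the two end knots
    lo = r < rt[0]
    hi = r > rt[-1]
    if np.any(lo):
        slope = (gt[1] - gt[0]) / (rt[1] - rt[0])
        lng = np.where(lo, gt[0] + slope * (r - rt[0]), lng)
    if np.any(hi):
        slope = (gt[-1] - gt[-2]) / (rt[-1] - rt[-2])
        lng = np.where(hi, gt[-1] + slope * (r - rt[-1]), lng)
    out = np.exp(lng)
    return out if out.ndim else float(out)


def anisotropy(r_cm, theta_rad, dataset: TG43Dataset) -> np.ndarray:
    """F(r, theta): bilinear in (r, theta), folded onto [0, 90 deg], edge-clamped."""
    r = np.asarray(r_cm, dtype=float)
    theta = np.asarray(theta_rad, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    theta_deg = np.degrees(theta)
    theta_deg = np.where(theta_deg > 90.0, 180.0 - theta_deg, theta_deg)
    theta_deg = np.clip(theta_deg, 0.0, 90.0)
    rr = np.clip(r, dataset.aniso_r_cm[0], dataset.aniso_r_cm[-1])
    ir = np.clip(np.searchsorted(dataset.aniso_r_cm, rr) - 1, 0,
                 len(dataset.aniso_r_cm) - 2)
    it = np.clip(np.searchsorted(dataset.aniso_theta_deg, theta_deg) - 1, 0,
                 len(dataset.aniso_theta_deg) - 2)
    r1 = dataset.aniso_r_cm[ir]
    r2 = dataset.aniso_r_cm[ir + 1]
    t1 = dataset.aniso_theta_deg[it]
    t2 = dataset.aniso_theta_deg[it + 1]
    wr = np.where(r2 > r1, (rr - r1) / (r2 - r1), 0.0)
    wt = np.where(t2 > t1, (theta_deg - t1) / (t2 - t1), 0.0)
    f11 = dataset.aniso_f[ir, it]
    f12 = dataset.aniso_f[ir, it + 1]
    f21 = dataset.aniso_f[ir + 1, it]
    f22 = dataset.aniso_f[ir + 1, it + 1]
    out = (f11 * (1 - wr) * (1 - wt) + f12 * (1 - wr) * wt
           + f21 * wr * (1 - wt) + f22 * wr * wt)
    return out if out.ndim else float(out)


def _seed_frame(seed: SeedSource, points_mm: np.ndarray):
    """(r_cm, theta) of points relative to the seed."""
    d = (points_mm - np.asarray(seed.position)) / 10.0  # cm
    r = np.linalg.norm(d, axis=-1)
    if np.any(r == 0):
        raise ValueError("dose point coincides with seed position")
    cos_t = np.clip(d @ np.asarray(seed.axis) / r, -1.0, 1.0)
    return r, np.arccos(cos_t)


def dose_rate_single(seed: SeedSource, point_mm, dataset: TG43Dataset) -> float:
    """Dose rate (cGy/h) at a point from one seed."""
    pts = np.atleast_2d(np.asarray(point_mm, dtype=float))
    r, theta = _seed_frame(seed, pts)
    g_norm = geometry_factor_line(R0_CM, THETA0, dataset.active_length_cm)
    val = (seed.strength * dataset.dose_rate_constant
           * geometry_factor_line(r, theta, dataset.active_length_cm) / g_norm
           * radial_dose(r, dataset) * anisotropy(r, theta, dataset))
    return float(val[0]) if np.asarray(point_mm).ndim == 1 else val


def dose_grid_tg43(seeds, geometry: GridGeometry, dataset: TG43Dataset,
                   chunk_voxels: int = 2_000_000) -> DoseGrid:
    """Superposed TG-43 dose over a voxel grid (water formalism everywhere).

    A voxel centre coinciding with a seed is evaluated 0.1 mm off the seed
    along its axis (logged).
    """
    if not seeds:
        raise ValueError("at least one seed required")
    xs, ys, zs = geometry.voxel_centers()
    pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    dose = np.zeros(pts.shape[0])
    g_norm = geometry_factor_line(R0_CM, THETA0, dataset.active_length_cm)
    for seed in seeds:
        pos = np.asarray(seed.position)
        axis = np.asarray(seed.axis)
        for start in range(0, pts.shape[0], chunk_voxels):
            chunk = pts[start:start + chunk_voxels]
            d = (chunk - pos) / 10.0
            r = np.linalg.norm(d, axis=1)
            coincident = r < 1e-9
            if np.any(coincident):
                logger.warning("voxel centre coincides with a seed; offset 0.1 mm")
                d[coincident] = axis * 0.01
                r[coincident] = 0.01
            cos_t = np.clip(d @ axis / r, -1.0, 1.0)
            theta = np.arccos(cos_t)
            # guard on-axis points inside the active line
            half = dataset.active_length_cm / 2
            bad = (np.abs(np.sin(theta)) < 1e-8) & (r <= half)
            theta = np.where(bad, 0.05, theta)
            dose[start:start + chunk_voxels] += (
                seed.strength * dataset.dose_rate_constant
                * geometry_factor_line(r, theta, dataset.active_length_cm) / g_norm
                * radial_dose(r, dataset) * anisotropy(r, theta, dataset))
    grid = dose.reshape(geometry.shape)
    return DoseGrid(geometry, grid, metadata={
        "engine": "tg43", "units": "cGy/h",
        "dose_rate_constant": dataset.dose_rate_constant,
        "n_seeds": len(seeds)})


def normalize_to_prescription(grid: DoseGrid, point_mm, prescription_gy: float):
    """Scale a grid so the trilinear dose at ``point_mm`` equals the prescription.

    Returns (scaled grid, scale factor).  The same factor is meant to be
    applied to a matched Monte Carlo grid (the paper's convention of scaling
    everything by the TG-43 value at the prescription point).
    """
    ref = trilinear(grid.geometry, grid.dose, point_mm)
    if ref <= 0:
        raise ValueError("zero dose at normalization point")
    scale = prescription_gy / ref
    out = grid.scaled(scale)
    out.metadata.update({"units": "Gy", "prescription_gy": prescription_gy,
                         "prescription_point_mm": tuple(np.asarray(point_mm, float)),
                         "normalization_reference": ref})
    return out, scale
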