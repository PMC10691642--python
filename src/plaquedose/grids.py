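"""Dose-grid containers and geometry helpers.

All spatial quantities are in millimetres; doses carry whatever unit the
producing engine declares in ``DoseGrid.metadata['units']`` (the planning
layer renormalises everything to the prescription, so absolute units only
matter for bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Regular voxel grid: ``origin`` is the centre of voxel (0, 0, 0)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid must contain at least one voxel")

    @classmethod
    def centered(cls, extent_mm, spacing) -> "GridGeometry":
        """Grid of the given extent whose centre voxel maps to (0, 0, 0)."""
        extent = np.asarray(extent_mm, dtype=float)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        shape = np.maximum(np.round(extent / spacing).astype(int), 1)
        origin = -(shape - 1) / 2.0 * spacing
        return cls(tuple(origin), tuple(spacing), tuple(int(n) for n in shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self):
        """Meshgrid (ij indexing) of voxel-centre coordinates."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) * 1e-3

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        lo = np.asarray(self.origin) - np.asarray(self.spacing) / 2
        hi = lo + np.asarray(self.spacing) * np.asarray(self.shape)
        return bool(np.all(p >= lo) and np.all(p <= hi))


@dataclass
class DoseGrid:
    """Per-voxel dose with per-voxel relative statistical uncertainty."""

    geometry: GridGeometry
    dose: np.ndarray
    uncertainty: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.geometry.shape:
            raise ValueError("dose array does not match grid shape")
        if self.uncertainty is None:
            self.uncertainty = np.zeros_like(self.dose)
        if np.any(self.dose < 0):
            raise ValueError("negative dose")

    def scaled(self, factor: float) -> "DoseGrid":
        meta = dict(self.metadata)
        meta["scale_factor"] = meta.get("scale_factor", 1.0) * factor
        return DoseGrid(self.geometry, self.dose * factor,
                        self.uncertainty.copy(), meta)

    def probe(self, point, with_uncertainty: bool = False):
        """Trilinear interpolation at an arbitrary interior point (mm)."""
        value = trilinear(self.geometry, self.dose, point)
        if not with_uncertainty:
            return value
        unc = trilinear(self.geometry, self.uncertainty, point)
        return value, unc

    def profile(self, axis: int, through) -> "np.ndarray":
        """Dose samples along a grid axis through an arbitrary point.

        Returns a (n, 2) array of coordinate (mm) and dose.
        """
        coords = self.geometry.axis_coords(axis)
        out = np.empty((len(coords), 2))
        p = np.asarray(through, dtype=float).copy()
        for i, c in enumerate(coords):
            p[axis] = c
            out[i, 0] = c
            out[i, 1] = trilinear(self.geometry, self.dose, p)
        return out


def trilinear(geometry: GridGeometry, values: np.ndarray, point) -> float:
    """Trilinear interpolation of a voxel-centre field; errors outside grid."""
    p = np.asarray(point, dtype=float)
    if not geometry.contains(p):
        raise ValueError(f"point {tuple(p)} outside grid")
    f = (p - np.asarray(geometry.origin)) / np.asarray(geometry.spacing)
    i0 = np.floor(f).astype(int)
    # clamp so that edge points use the boundary cell
    i0 = np.clip(i0, 0, np.asarray(geometry.shape) - 2)
    # degenerate single-voxel axes
    i0 = np.minimum(i0, np.maximum(np.asarray(geometry.shape) - 2, 0))
    t = f - i0
    t = np.clip(t, 0.0, 1.0)
    acc = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = np.minimum(i0 + (dx, dy, dz), np.asarray(geometry.shape) - 1)
                wgt = ((t[0] if dx else 1 - t[0])
                       * (t[1] if dy else 1 - t[1])
                       * (t[2] if dz else 1 - t[2]))
                acc += wgt * values[tuple(idx)]
    return float(acc)


def save_nifti(grid: DoseGrid, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(grid.geometry.spacing) + [1.0])
    affine[:3, 3] = grid.geometry.origin
    img = nib.Nifti1Image(grid.dose.astype(np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> DoseGrid:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj, dtype=float)
    geom = GridGeometry(origin, spacing, data.shape)
    return DoseGrid(geom, data)
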