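"""Simplified voxelized photon Monte Carlo for low-energy brachytherapy.

Photon-only transport (electrons deposit locally; the 1.5 MeV electron
cutoff of the reference configuration is equivalent to not transporting
them at all at I-125 energies) with

* exact voxel-boundary ray marching (Amanatides-Woo DDA) — every traversed
  segment contributes to the track-length collision-kerma estimator of its
  voxel, so delta tracking would buy nothing here;
* photoelectric absorption (terminates the photon; fluorescence deposited
  locally via the energy-absorption coefficient), free-electron
  Klein-Nishina Compton sampling (Kahn's method) and Thomson-distributed
  Rayleigh scattering;
* seeds modelled as transport-transparent line emitters: positions sampled
  uniformly along the 3 mm active length, directions isotropic or weighted
  by the seed polar anisotropy F(1 cm, theta) with compensating statistical
  weights (the capsule's self-absorption enters through the weights, not
  through transported material);
* history-batch statistics: the run is split into batches and the per-voxel
  relative standard uncertainty is the standard error over batch means.

Doses are reported per emitted history in keV/g; all downstream analysis is
carried out after normalisation to the prescription, so absolute unit
conversion is never needed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .grids import DoseGrid, GridGeometry
from .materials import (ENERGY_GRID_KEV, EmissionSpectrum, MATERIAL_ORDER,
                        i125_spectrum, material_table_stack)
from .tg43 import TG43Dataset, anisotropy as _f_aniso

ACTIVE_LENGTH_MM = 3.0
DEFAULT_CUTOFF_KEV = 1.0
DEFAULT_BATCHES = 20


# ----------------------------------------------------------------- sampling

def mean_anisotropy(dataset: TG43Dataset) -> float:
    """Solid-angle average of F(1 cm, theta) (the 1-cm anisotropy factor)."""
    theta = np.linspace(0.0, np.pi, 721)
    f = _f_aniso(np.full_like(theta, 1.0), theta, dataset)
    return float(np.trapezoid(f * np.sin(theta), theta) / 2.0)


def sample_emissions(seeds, n: int, mode: str, rng: np.random.Generator,
                     dataset: TG43Dataset | None = None,
                     spectrum: EmissionSpectrum | None = None):
    """Photon batch (positions mm, directions, energies keV, weights).

    Photons are apportioned to seeds with probability proportional to
    air-kerma strength; positions are drawn uniformly along each seed's
    active length; ``anisotropy_weighted`` mode keeps isotropic directions
    but attaches weights F(1 cm, theta)/<F> so the weighted mean is unbiased.
    """
    if n < 1:
        raise ValueError("need at least one photon")
    if not seeds:
        raise ValueError("no seeds")
    spectrum = spectrum or i125_spectrum()
    strengths = np.array([s.strength for s in seeds], dtype=float)
    total = strengths.sum()
    if total <= 0:
        raise ValueError("all seed strengths are zero")
    idx = rng.choice(len(seeds), size=n, p=strengths / total)
    pos = np.array([s.position for s in seeds], dtype=float)[idx]
    axes = np.array([s.axis for s in seeds], dtype=float)[idx]
    pos = pos + (rng.uniform(-0.5, 0.5, n) * ACTIVE_LENGTH_MM)[:, None] * axes
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    dirs = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    if mode == "anisotropy_weighted":
        if dataset is None:
            raise ValueError("anisotropy_weighted mode needs a TG43Dataset")
        cos_axis = np.clip(np.einsum("ij,ij->i", dirs, axes), -1.0, 1.0)
        f = _f_aniso(np.ones(n), np.arccos(cos_axis), dataset)
        weights = f / mean_anisotropy(dataset)
    elif mode == "isotropic":
        weights = np.ones(n)
    else:
        raise ValueError(f"unknown emission mode {mode!r}")
    energies = rng.choice(spectrum.energies_kev, size=n,
                          p=spectrum.probabilities)
    return pos, dirs, energies.astype(float), weights


# ------------------------------------------------------------ numba kernels

@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.999999:
        sign = 1.0 if uz > 0 else -1.0
        return sint * cp, sint * sp, cost * sign
    a = math.sqrt(1.0 - uz * uz)
    nx = ux * cost + sint * (ux * uz * cp - uy * sp) / a
    ny = uy * cost + sint * (uy * uz * cp + ux * sp) / a
    nz = uz * cost - sint * a * cp
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _kahn(k):
    """Klein-Nishina sampling; returns (E/E', cos theta)."""
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * k) / (9.0 + 2.0 * k):
            x = 1.0 + 2.0 * k * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                return x, 1.0 - (x - 1.0) / k
        else:
            x = (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2)
            c = 1.0 - (x - 1.0) / k
            if r3 <= 0.5 * (c * c + 1.0 / x):
                return x, c


@njit(cache=True, inline="always")
def _thomson_cos():
    while True:
        mu = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + mu * mu):
            return mu


@njit(cache=True, inline="always")
def _rayleigh_cos(e_kev, x0):
    """Coherent-scattering angle from the Thomson distribution screened by
    an effective-Z atomic form factor, F ~ (1 + (x/x0)^2)^-1.5 with
    x = sin(theta/2) E / 12.398 (inverse Angstrom momentum transfer)."""
    while True:
        mu = _thomson_cos()
        x = e_kev / 12.398 * math.sqrt(0.5 * (1.0 - mu))
        t = 1.0 + (x / x0) ** 2
        if np.random.random() <= 1.0 / (t * t * t):
            return mu


@njit(cache=True, inline="always")
def _fill_local(e, loge0, dloge, lmu, lpe, lcoh, lmuen,
                mu01, pe01, coh01, muen01):
    nmat, ne = lmu.shape
    f = (math.log(e) - loge0) / dloge
    i0 = int(f)
    if i0 < 0:
        i0 = 0
    elif i0 > ne - 2:
        i0 = ne - 2
    fr = f - i0
    for m in range(nmat):
        mu01[m] = math.exp(lmu[m, i0] * (1 - fr) + lmu[m, i0 + 1] * fr) * 0.1
        pe01[m] = math.exp(lpe[m, i0] * (1 - fr) + lpe[m, i0 + 1] * fr) * 0.1
        coh01[m] = math.exp(lcoh[m, i0] * (1 - fr) + lcoh[m, i0 + 1] * fr) * 0.1
        muen01[m] = math.exp(lmuen[m, i0] * (1 - fr)
                             + lmuen[m, i0 + 1] * fr) * 0.1


@njit(cache=True)
def _transport_kernel(pos, dirs, energy, weight, labels, density,
                      origin, spacing, lmu, lpe, lcoh, lmuen, ray_x0,
                      loge0, dloge, cutoff_kev, max_scatters, tally, seed):
    """Track a photon batch through the voxel grid, scoring track length x
    mu_en/rho x E (keV * cm^2/g, with lengths folded in as 0.1/mm = cm)."""
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    nmat = lmu.shape[0]
    mu01 = np.empty(nmat)
    pe01 = np.empty(nmat)
    coh01 = np.empty(nmat)
    muen01 = np.empty(nmat)
    ox, oy, oz = origin[0], origin[1], origin[2]
    dx, dy, dz = spacing[0], spacing[1], spacing[2]
    lox, loy, loz = ox - 0.5 * dx, oy - 0.5 * dy, oz - 0.5 * dz
    hix, hiy, hiz = lox + nx * dx, loy + ny * dy, loz + nz * dz
    big = 1e30
    for i in range(pos.shape[0]):
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        ux = dirs[i, 0]
        uy = dirs[i, 1]
        uz = dirs[i, 2]
        e = energy[i]
        w = weight[i]
        if e < cutoff_kev:
            continue
        # advance to the grid box if emitted outside it
        if not (lox <= x < hix and loy <= y < hiy and loz <= z < hiz):
            tmin = 0.0
            tmax = big
            ok = True
            for ax in range(3):
                if ax == 0:
                    p0, u, lo, hi = x, ux, lox, hix
                elif ax == 1:
                    p0, u, lo, hi = y, uy, loy, hiy
                else:
                    p0, u, lo, hi = z, uz, loz, hiz
                if abs(u) < 1e-12:
                    if p0 < lo or p0 > hi:
                        ok = False
                        break
                else:
                    t1 = (lo - p0) / u
                    t2 = (hi - p0) / u
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > tmin:
                        tmin = t1
                    if t2 < tmax:
                        tmax = t2
            if (not ok) or tmax <= tmin:
                continue
            t_in = tmin + 1e-9
            x += ux * t_in
            y += uy * t_in
            z += uz * t_in
        _fill_local(e, loge0, dloge, lmu, lpe, lcoh, lmuen,
                    mu01, pe01, coh01, muen01)
        n_scat = 0
        alive = True
        while alive:
            # (re)initialise DDA from current position/direction
            ix = int((x - lox) / dx)
            iy = int((y - loy) / dy)
            iz = int((z - loz) / dz)
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                break
            if ux > 0:
                step_x = 1
                tmaxx = (lox + (ix + 1) * dx - x) / ux
                tdx = dx / ux
            elif ux < 0:
                step_x = -1
                tmaxx = (lox + ix * dx - x) / ux
                tdx = -dx / ux
            else:
                step_x = 0
                tmaxx = big
                tdx = big
            if uy > 0:
                step_y = 1
                tmaxy = (loy + (iy + 1) * dy - y) / uy
                tdy = dy / uy
            elif uy < 0:
                step_y = -1
                tmaxy = (loy + iy * dy - y) / uy
                tdy = -dy / uy
            else:
                step_y = 0
                tmaxy = big
                tdy = big
            if uz > 0:
                step_z = 1
                tmaxz = (loz + (iz + 1) * dz - z) / uz
                tdz = dz / uz
            elif uz < 0:
                step_z = -1
                tmaxz = (loz + iz * dz - z) / uz
                tdz = -dz / uz
            else:
                step_z = 0
                tmaxz = big
                tdz = big
            tau = -math.log(np.random.random())
            t = 0.0
            interacted = False
            escaped = False
            while True:
                m = labels[ix, iy, iz]
                rho = density[ix, iy, iz]
                mu = mu01[m] * rho  # per mm
                tnext = tmaxx
                if tmaxy < tnext:
                    tnext = tmaxy
                if tmaxz < tnext:
                    tnext = tmaxz
                seg = tnext - t
                if mu * seg >= tau and mu > 0.0:
                    ell = tau / mu
                    tally[ix, iy, iz] += w * e * muen01[m] * ell
                    t += ell
                    x += ux * t
                    y += uy * t
                    z += uz * t
                    interacted = True
                    break
                tally[ix, iy, iz] += w * e * muen01[m] * seg
                tau -= mu * seg
                t = tnext
                if tmaxx <= tmaxy and tmaxx <= tmaxz:
                    ix += step_x
                    tmaxx += tdx
                    if ix < 0 or ix >= nx:
                        escaped = True
                        break
                elif tmaxy <= tmaxz:
                    iy += step_y
                    tmaxy += tdy
                    if iy < 0 or iy >= ny:
                        escaped = True
                        break
                else:
                    iz += step_z
                    tmaxz += tdz
                    if iz < 0 or iz >= nz:
                        escaped = True
                        break
            if escaped or not interacted:
                break
            # interaction in material m
            if n_scat >= max_scatters:
                break
            xi = np.random.random() * mu01[m]
            if xi < pe01[m]:
                break  # photoelectric absorption
            phi = 2.0 * math.pi * np.random.random()
            if xi < pe01[m] + coh01[m]:
                cosang = _rayleigh_cos(e, ray_x0[m])
            else:
                ratio, cosang = _kahn(e / 510.99895)
                e = e / ratio
                if e < cutoff_kev:
                    break
                _fill_local(e, loge0, dloge, lmu, lpe, lcoh, lmuen,
                            mu01, pe01, coh01, muen01)
            ux, uy, uz = _rotate(ux, uy, uz, cosang, phi)
            n_scat += 1
    return tally


def rayleigh_screening(fractions: dict[str, float]) -> float:
    """Screening parameter x0 (inverse Angstrom) of the effective-Z atomic
    form factor used for coherent-scattering angles; elements weighted by
    their share of the coherent cross section (~Z^2.5)."""
    from .materials import _ELEMENTS

    num = 0.0
    den = 0.0
    for el, w in fractions.items():
        z, a = _ELEMENTS[el][0], _ELEMENTS[el][1]
        share = w / a * z**2.5
        num += share * z
        den += share
    z_eff = num / den
    return 0.33 * z_eff ** (1.0 / 3.0)


class _KernelData:
    """Cached log-space material tables shared by all runs."""

    def __init__(self) -> None:
        from .materials import MATERIAL_ORDER, get_material

        mu, pe, coh, mu_en, rho = material_table_stack()
        self.ray_x0 = np.array([rayleigh_screening(get_material(n).fractions)
                                for n in MATERIAL_ORDER])
        self.lmu = np.log(mu)
        self.lpe = np.log(np.maximum(pe, 1e-30))
        self.lcoh = np.log(np.maximum(coh, 1e-30))
        self.lmuen = np.log(mu_en)
        self.densities = rho
        self.loge0 = float(np.log(ENERGY_GRID_KEV[0]))
        self.dloge = float(np.log(ENERGY_GRID_KEV[1])
                           - np.log(ENERGY_GRID_KEV[0]))


_KDATA: _KernelData | None = None


def _kernel_data() -> _KernelData:
    global _KDATA
    if _KDATA is None:
        _KDATA = _KernelData()
    return _KDATA


# --------------------------------------------------------------- public API

def transport(batch, labels: np.ndarray, density: np.ndarray,
              geometry: GridGeometry, cutoff_kev: float = DEFAULT_CUTOFF_KEV,
              max_scatters: int = 10_000, seed: int = 0) -> np.ndarray:
    """Transport one photon batch; returns the raw track-length tally grid
    (keV * cm^2/g per voxel, to be divided by voxel volume)."""
    if cutoff_kev < 1.0:
        raise ValueError("cutoff below the 1 keV table floor")
    pos, dirs, energies, weights = batch
    kd = _kernel_data()
    tally = np.zeros(labels.shape, dtype=np.float64)
    _transport_kernel(np.ascontiguousarray(pos), np.ascontiguousarray(dirs),
                      np.ascontiguousarray(energies),
                      np.ascontiguousarray(weights),
                      labels, density,
                      np.asarray(geometry.origin, dtype=np.float64),
                      np.asarray(geometry.spacing, dtype=np.float64),
                      kd.lmu, kd.lpe, kd.lcoh, kd.lmuen, kd.ray_x0,
                      kd.loge0, kd.dloge, float(cutoff_kev),
                      max_scatters, tally, int(seed) % 2**31)
    return tally


def score_kerma(batch_means,
                geometry: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-batch mean tallies into dose per history and relative
    standard uncertainty (standard error over batches).

    ``batch_means`` may be any iterable (a generator keeps only running
    sums in memory, which matters for fine grids).
    """
    stack_sum = None
    stack_sq = None
    nb = 0
    for bm in batch_means:
        if stack_sum is None:
            stack_sum = np.zeros_like(bm)
            stack_sq = np.zeros_like(bm)
        stack_sum += bm
        stack_sq += bm * bm
        nb += 1
    if nb < 2:
        raise ValueError("need at least two batches for uncertainty")
    mean = stack_sum / nb
    var = np.maximum(stack_sq / nb - mean**2, 0.0) / (nb - 1)
    dose = mean / geometry.voxel_volume_cm3
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, np.sqrt(var) / np.maximum(mean, 1e-300), 0.0)
    return dose, rel


def run_engine(phantom, seeds, mode: str, histories: int, seed: int,
               dataset: TG43Dataset, spectrum: EmissionSpectrum | None = None,
               batches: int = DEFAULT_BATCHES,
               emission: str = "anisotropy_weighted",
               cutoff_kev: float = DEFAULT_CUTOFF_KEV) -> DoseGrid:
    """Run the Monte Carlo on a voxel phantom.

    ``mode='tg43_water'`` replaces every voxel by water (plaque and seed
    bodies absent) to emulate a TG-43-condition calculation; ``mode='full'``
    transports through the phantom's materials as given (the plaque must
    already be embedded in its label grid).
    """
    if histories < batches:
        raise ValueError("histories must be >= number of batches")
    geometry: GridGeometry = phantom.geometry
    if mode == "tg43_water":
        labels = np.zeros(geometry.shape, dtype=np.uint8)  # all water
        density = np.full(geometry.shape, 0.998, dtype=np.float32)
    elif mode == "full":
        labels = np.ascontiguousarray(phantom.labels)
        density = np.ascontiguousarray(phantom.density)
        if labels.max() >= len(MATERIAL_ORDER):
            raise ValueError("phantom contains unmapped material labels")
    else:
        raise ValueError(f"unknown engine mode {mode!r}")
    spectrum = spectrum or i125_spectrum()
    rng = np.random.default_rng(seed)
    per_batch = histories // batches

    def _batches():
        for b in range(batches):
            batch = sample_emissions(seeds, per_batch, emission, rng,
                                     dataset=dataset, spectrum=spectrum)
            tally = transport(batch, labels, density, geometry,
                              cutoff_kev=cutoff_kev,
                              seed=(seed + 7919 * (b + 1)) % 2**31)
            yield tally / per_batch

    dose, rel = score_kerma(_batches(), geometry)
    return DoseGrid(geometry, dose, rel, metadata={
        "engine": "mc", "mode": mode, "emission": emission,
        "histories": per_batch * batches, "batches": batches,
        "rng_seed": int(seed), "units": "keV/g per history",
        "traversal": "voxel-boundary DDA", "cutoff_keV": cutoff_kev})


# ----------------------------- homogeneous-medium engine (dataset + oracles)

@njit(cache=True)
def _homog_kernel(n, seed, half_len_mm, line_e, line_cdf,
                  f_theta, f_mean, lmu, lpe, lcoh, lmuen, ray_x0,
                  loge0, dloge,
                  rho, r_edges_mm, band_cos, escape_mm, max_scatters,
                  cutoff_kev, tally):
    """Line source at the origin (axis = z) in an unbounded homogeneous
    medium; scores track length x E x mu_en/rho into radial shells
    restricted to |cos polar| < band_cos about the transverse plane."""
    np.random.seed(seed)
    ne = lmu.shape[0]
    nbins = r_edges_mm.shape[0] - 1
    for i in range(n):
        # emission
        u = np.random.random()
        e = line_e[0]
        for j in range(line_e.shape[0]):
            if u <= line_cdf[j]:
                e = line_e[j]
                break
        zpos = (np.random.random() - 0.5) * 2.0 * half_len_mm
        x = 0.0
        y = 0.0
        z = zpos
        cost = 2.0 * np.random.random() - 1.0
        phi = 2.0 * math.pi * np.random.random()
        sint = math.sqrt(1.0 - cost * cost)
        ux = sint * math.cos(phi)
        uy = sint * math.sin(phi)
        uz = cost
        # anisotropy weight about the z axis
        ang = math.acos(abs(cost)) if abs(cost) <= 1.0 else 0.0
        idx = ang / (0.5 * math.pi) * (f_theta.shape[0] - 1)
        i0 = int(idx)
        if i0 > f_theta.shape[0] - 2:
            i0 = f_theta.shape[0] - 2
        fr = idx - i0
        w = (f_theta[i0] * (1 - fr) + f_theta[i0 + 1] * fr) / f_mean
        n_scat = 0
        while True:
            # interpolate coefficients at e
            f = (math.log(e) - loge0) / dloge
            j0 = int(f)
            if j0 < 0:
                j0 = 0
            elif j0 > ne - 2:
                j0 = ne - 2
            fr2 = f - j0
            mu_cm = math.exp(lmu[j0] * (1 - fr2) + lmu[j0 + 1] * fr2) * rho
            pe_cm = math.exp(lpe[j0] * (1 - fr2) + lpe[j0 + 1] * fr2) * rho
            coh_cm = math.exp(lcoh[j0] * (1 - fr2) + lcoh[j0 + 1] * fr2) * rho
            muen = math.exp(lmuen[j0] * (1 - fr2) + lmuen[j0 + 1] * fr2)
            s_mm = -math.log(np.random.random()) / mu_cm * 10.0
            # march the flight in substeps, depositing at midpoints; the
            # first substep is phase-jittered so deterministic step
            # boundaries along radial rays cannot alias with the bins
            travelled = 0.0
            first = True
            while travelled < s_mm:
                r_now = math.sqrt(x * x + y * y + z * z)
                step = 0.1 * r_now
                if step < 0.05:
                    step = 0.05
                if step > 2.0:
                    step = 2.0
                if first:
                    step *= 0.01 + 0.99 * np.random.random()
                    first = False
                if travelled + step > s_mm:
                    step = s_mm - travelled
                mx = x + ux * (step * 0.5)
                my = y + uy * (step * 0.5)
                mz = z + uz * (step * 0.5)
                rm = math.sqrt(mx * mx + my * my + mz * mz)
                if rm > 0.0 and abs(mz / rm) < band_cos:
                    # locate radial bin (linear search is fine: few bins)
                    for b in range(nbins):
                        if r_edges_mm[b] <= rm < r_edges_mm[b + 1]:
                            tally[b] += w * e * muen * (step * 0.1)
                            break
                x += ux * step
                y += uy * step
                z += uz * step
                travelled += step
            r_now = math.sqrt(x * x + y * y + z * z)
            if r_now > escape_mm:
                break
            if n_scat >= max_scatters:
                break
            xi = np.random.random() * mu_cm
            if xi < pe_cm:
                break
            sphi = 2.0 * math.pi * np.random.random()
            if xi < pe_cm + coh_cm:
                cosang = _rayleigh_cos(e, ray_x0)
            else:
                ratio, cosang = _kahn(e / 510.99895)
                e = e / ratio
                if e < cutoff_kev:
                    break
            ux, uy, uz = _rotate(ux, uy, uz, cosang, sphi)
            n_scat += 1
    return tally


def homogeneous_radial_kerma(material_name: str, r_edges_mm: np.ndarray,
                             histories: int, seed: int,
                             f_theta: np.ndarray | None = None,
                             spectrum: EmissionSpectrum | None = None,
                             band_cos: float = 0.3,
                             half_length_mm: float = ACTIVE_LENGTH_MM / 2,
                             max_scatters: int = 10_000,
                             escape_mm: float = 160.0) -> np.ndarray:
    """Kerma per unit volume in transverse-band radial shells around a line
    source in an unbounded medium.  Used to generate the packaged radial
    dose function and as a voxel-free cross-check in tests."""
    from .materials import get_material

    mat = get_material(material_name)
    spectrum = spectrum or i125_spectrum()
    if f_theta is None:
        f_theta = np.ones(91)
    f_theta = np.asarray(f_theta, dtype=float)
    theta = np.linspace(0.0, np.pi / 2, len(f_theta))
    f_mean = float(np.trapezoid(f_theta * np.sin(theta), theta))  # = <F>
    tally = np.zeros(len(r_edges_mm) - 1)
    _homog_kernel(int(histories), int(seed) % 2**31, half_length_mm,
                  spectrum.energies_kev,
                  np.cumsum(spectrum.probabilities),
                  f_theta, f_mean,
                  np.log(mat.mu), np.log(np.maximum(mat.pe, 1e-30)),
                  np.log(np.maximum(mat.coh, 1e-30)), np.log(mat.mu_en),
                  rayleigh_screening(mat.fractions),
                  float(np.log(ENERGY_GRID_KEV[0])),
                  float(np.log(ENERGY_GRID_KEV[1]) - np.log(ENERGY_GRID_KEV[0])),
                  mat.density, np.asarray(r_edges_mm, dtype=float),
                  float(band_cos), float(escape_mm), int(max_scatters),
                  DEFAULT_CUTOFF_KEV, tally)
    # per-history kerma density: divide by shell-band volume (cm^3)
    r = np.asarray(r_edges_mm, dtype=float) / 10.0  # cm
    vol = 4.0 / 3.0 * np.pi * (r[1:]**3 - r[:-1]**3) * band_cos
    return tally / histories / vol
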