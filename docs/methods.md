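# Methods

This note records the models behind `plaquedose`, the parameters that
matter, and the choices made where the design was genuinely open.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate frame and geometry

All engines share one plaque-centric frame: the plaque central axis is +z
pointing into the eye; the concave silastic apex touches the outer sclera
at (0, 0, −1) mm; the inner sclera crosses the axis at z = 0; the
prescription point is (0, 0, 5) mm (tumor apex, 5 mm from the inner
sclera).  The globe (default outer diameter 24.6 mm, 1 mm sclera) and the
plaque share the centre of curvature (0, 0, 11.3) mm, i.e. the plaque is
conformal to the eye.  Supporting this choice: the published peripheral
comparison points, (7.7, 0, 3) mm for the 16 mm plaque and (9.5, 0, 5.1) mm
for the notched plaque, both lie on the inner-sclera sphere of exactly this
globe.

### Plaque model

Spherical-cap shell: silastic from radius 12.3 mm (the radius of curvature
of the concave face, the COMS engineering reading of "plaque radius") to
14.55 mm, gold alloy (modulay, Au/Ag/Cu/Pd 77/14/8/1 wt%, 15.8 g cm⁻³)
from 14.55 to 15.05 mm.  The nominal diameter (16 / 20 mm) is the chord
diameter of the concave footprint, fixing the cap half-angle (40.6° /
54.4°).  A 0.5 mm full-thickness gold band beyond the cap angle models the
rim lip with which the gold shell wraps the silastic edge; both published
comparison points sit angularly at the rim, so the lip measurably affects
the heterogeneous results.  The notch is a cylindrical cut (radius 4 mm,
axis parallel to z at x = −9 mm) lined by a 0.5 mm gold wall; slots whose
4.5 × 0.8 mm seed envelope intersects the wall-dilated cut are removed.

### Seed slots

The original layout drawings are not public at coordinate precision, so
the slots are constructed as rings on the sphere 1 mm above the concave
face (radius 13.3 mm), seed long axes tangent to the rings, and the free
angles were fixed once against the published planning facts: the uniform
16 mm plan must put the comparison point at ~100% of prescription (that is
the point's definition), the non-uniform plans must reproduce the published
comparison percentages, and the uniform and non-uniform 16 mm cumulative
DVHs must essentially overlay.  The result:

| preset | rings (polar angle × count) | strength groups |
|---|---|---|
| 16 mm | 25.9° × 8, 20.7° × 4, centre × 1 | 1 = middle ring (4.4 U), 2 = outer (2.14 U), 3 = centre (1.02 U) |
| 20 mm | 45.25° × 12, 26.0° × 8 (meridional), 14.0° × 4 | 1 = inner (3.46 U), 2 = outer (1.76 U), 3 = middle (0.85 U) |

The 20 mm intermediate ring is meridional (axes along the meridian): eight
circumferential 4.5 mm seeds do not physically fit on the fitted ring
radius.  The notched preset keeps 20 of the 24 slots.  This layout is a
reconstruction constrained by published doses, not a copy of the vendor
drawing; the slot tables ship as CSV resources.

## TG-43 engine

Standard 2D line-source formalism.  Packaged dataset:
Λ = 0.965 cGy h⁻¹ U⁻¹ and L = 3.0 mm (the accepted 6711-type values);
g_L(r) on 21 knots from 1.5 mm to 10 cm, generated by the package's own
homogeneous-medium Monte Carlo (transverse-band track-length estimator
around a bare 3 mm line source) in a 5 cm-radius water medium matching the
10 cm scoring box; F(θ), radius-independent, a smooth polar table with the
strong end suppression characteristic of the 6711's silver rod
(F(0°) = 0.36, rising to 1 at 90°).  Generating g_L with the package's own
transport (rather than embedding a literature table) makes the TG-43 and
Monte Carlo engines mutually consistent by construction — the water-mode
MC divided by the TG-43 grid is trend-free — at the cost that g_L carries
this package's cross-section model; since every reported quantity is a
dose *ratio* under prescription normalisation, Λ and the absolute scale of
g_L cancel throughout.  Interpolation: log-linear in r for g_L (log-linear
extrapolation beyond both ends), bilinear with edge clamping for F.
Implant duration and source decay are not modelled: the 85 Gy prescription
normalisation makes them cancel.

## Photon interaction data

Coefficients are built from a compact atomic model on a 96-point
log-energy grid (1–40 keV): free-electron Klein–Nishina incoherent
scattering with a binding factor E/(E+2.8 keV); a calibrated Z^2.5/A
coherent power law (E^−1.9); per-element photoelectric anchors at 30 keV
with power-law scaling (exponent 3.15 low-Z, ~2.9 high-Z) and a Z^4.5
interpolation for trace elements.  No edge structure: all I-125 lines lie
above the Ag/Pd K-edges and far below Au's.  μ_en assumes local deposition
of fluorescence and Compton-electron energy (photon-only transport;
electron ranges at these energies are sub-voxel).  Water reproduces the
standard reference values within ~2% (μ) and ~5% (μ_en) over 15–40 keV
(asserted in tests).  Tissues: ICRU-like soft tissue for sclera/lens/nerve
(densities 1.05/1.07/1.04), water-equivalent tumor at 1.05 g cm⁻³ and
vitreous at 1.005 — the TG-43-vs-MC contrast is dominated by the plaque
materials, so the tissue surrogate costs little.

## Monte Carlo transport

Photon-only, 1–40 keV, emitted from transparent 3 mm line sources
(positions uniform along the active length; directions isotropic with
compensating weights F(θ)/⟨F⟩, which represents capsule self-absorption
without transporting capsule material; inter-seed attenuation is
neglected).  Exact voxel-boundary ray marching (Amanatides–Woo) with
track-length collision-kerma scoring — every traversed segment deposits
w·E·(μ_en/ρ)·ℓ in its voxel, so the estimator converges far faster than an
interaction-density tally and delta-tracking would save nothing.
Interactions: photoelectric (terminate), Compton (Kahn's Klein–Nishina
sampling, free electron), Rayleigh (Thomson distribution screened by an
effective-Z atomic form factor).  Cutoff 1 keV.  Uncertainty: 20 history
batches; per-voxel relative standard error over batch means.  RNG seeds are
recorded in grid metadata and every run is reproducible bit-for-bit.

A second, voxel-free homogeneous-medium kernel (used for dataset
generation and closed-form oracles) shares the same physics; its
flight-marching substeps are phase-jittered so deterministic step ladders
along radial rays cannot alias with thin scoring shells.

### Engine bridging

An MC run reports dose per emitted history.  The factor to the TG-43
absolute scale is obtained per loading by regressing the analytic TG-43
dose on a water-mode MC run of the same loading along the central axis
(z = 5–20 mm, variance-weighted); because water-mode MC reproduces the
TG-43 field shape by construction, the factor is shape-independent.  The
same factor then converts any full-mode grid of that loading, which is how
heterogeneous doses are expressed as percentages of the TG-43 prescription
dose and how eye-phantom MC grids inherit the 85 Gy normalisation factor
of their TG-43 companion.

## Phantoms

Water box: 10 cm cube, 1 mm voxels (the published scoring convention) for
water-mode runs; full-mode runs score on a 0.39 × 0.39 × 0.4 mm grid over
the same cube so the 0.5 mm gold shell is resolved (occupancy-weighted
densities conserve areal density in partial voxels).

Eye phantom: 60 × 60 × 50 mm at 0.39 × 0.39 × 0.4 mm.  Analytic solids —
globe with sclera shell, ellipsoidal lens, cylindrical optic nerve + sheath
(5 mm diameter; the nerve head pierces the sclera to the optic disc), dome
tumor (spherical cap, base 12 mm, apex 5 mm) on the inner sclera — with
priority tumor > lens > nerve > sclera > vitreous > tissue.  In the
juxtapapillary configuration the nerve runs coaxially with the notch
(1 mm soft-tissue ring between sheath and gold wall, as in the reference
arrangement) and the tumor dome is shifted 1 mm toward the nerve so its
rasterised base genuinely reaches the optic disc (the dome–sclera
intersection circle is smaller than the nominal base).  The notch-cut
interior is recorded as a mask and excluded from notched-case DVH
reporting, mirroring the reference workflow.  The phantom is **not**
embedded in the surrounding water box for transport; the ≥18 mm soft-tissue
margin provides most of the scatter, and the residual boundary deficit
(~1–2% at peripheral structures) is well inside the tolerances used.

What the synthetic phantom does not emulate: CT-number heterogeneity,
real ocular compositions, anatomical asymmetry, and the authors' exact
contours.  Tests passing on it validate the dosimetric *method chain*
(geometry → transport → normalisation → DVH), not patient-specific values;
eye-phantom comparisons are therefore judged at ~10% tolerances.

## Planning and DVH conventions

Prescription 85 Gy at the apex point; matching criterion: both planning
points within ±5% (inclusive).  The loading search is an exhaustive
enumeration over group-wise assignments from the available strength set
with a per-assignment global scale freedom (minimax over the two points;
lexicographic tie-break).  cDVHs use 0.5 Gy bins on equal-volume voxels;
D_x% is the largest dose received by at least x% of the volume, linearly
interpolated between bin edges (so D95 is a near-minimum and D1 a
near-maximum).

## Problem sizes

Defaults chosen for single-CPU desk scale: 8 × 10⁶ histories for
water-mode runs, 1.2 × 10⁷ for full heterogeneous runs, 10⁷ for the eye
case, 20 batches everywhere (the reference configuration used 10¹⁰
histories; at our sizes the points of interest carry ≲1–2% relative
standard error, which the reported uncertainties make explicit).  The test
suite uses smaller sizes with the same seeds.

## Known limitations

- The polar anisotropy F is applied as an emission weight, but scattered
  photons partially fill in the polar cold regions, so the MC *dose*
  anisotropy is shallower than F itself: near the seed axis the MC exceeds
  the TG-43 prediction by up to ~10%, falling to ~1% at 50–60° — the same
  behaviour that makes the physical seed's measured F rise with radius.
  Central-axis quantities and the engine calibration are unaffected (the
  plaque's tangential seeds present their transverse planes to the axis);
  comparison-point percentages inherit a ≲1.5-point offset.
- Near-seed voxel tallies are heavy-tailed, so the batch-based standard
  errors there understate the true spread by a factor of ~2–3; tolerances
  on single-point comparisons keep an explicit floor for this reason.
- Transparent seeds: no inter-seed or capsule attenuation.  This is the
  main residual where many seeds sit between source and probe; the
  densely loaded notched rim comparison point is reproduced ~4 points high
  for exactly this reason, while the 16 mm point and the in-eye DVH
  metrics, where the effect is small, agree closely.
- Free-electron Compton and effective-Z Rayleigh angles; no edge
  structure or fluorescence transport (gold L X-rays deposited locally).
- The slot layout and the rim lip are constrained reconstructions, not
  vendor drawings; group-to-ring assignment is frozen per preset from the
  published planning doses.
- Single eye geometry; no left/right distinction beyond mirroring, no
  deformable anatomy, no DICOM input.
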