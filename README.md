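# plaquedose

Dosimetry of episcleral eye plaques for ocular melanoma: the clinical
water-formalism calculation (AAPM TG-43) side by side with a
heterogeneity-aware photon Monte Carlo, for standard COMS and notched
plaques with uniform or non-uniform I-125 seed loading.

Clinical eye-plaque planning prescribes 85 Gy to the tumor apex using the
TG-43 formalism, which assumes an all-water geometry.  Real plaques are not
water: the silastic seed carrier attenuates the ~28 keV I-125 photons, the
gold-alloy (modulay) backing is effectively opaque, and a notched plaque's
gold wall shields the optic nerve entirely.  This package quantifies what
the water formalism gets wrong, for the two planning situations used in
high-volume eye-cancer clinics: non-uniformly loaded standard plaques
matched to the uniform COMS distribution, and non-uniformly loaded notched
plaques placed around the optic nerve.

It is aimed at medical physicists and students who want a desk-scale,
fully inspectable model of eye-plaque dosimetry — not a clinical TPS.

## What is inside

- `plaquedose.tg43` — the TG-43 2D line-source formalism,
  `D(r,θ) = S_K Λ [G_L(r,θ)/G_L(r₀,θ₀)] g_L(r) F(r,θ)`, superposed over all
  seeds of a plan, with a packaged 6711-type dataset
  (Λ = 0.965 cGy h⁻¹ U⁻¹, L = 3 mm).
- `plaquedose.plaque` — constructive solid geometry of the COMS plaque
  (12.3 mm radius of curvature, 0.5 mm gold shell with rim lip, 2.25 mm
  silastic insert, seed-slot rings) and the 20 mm notched variant (8 mm
  diameter cylindrical cut at 9 mm offset, gold-lined).
- `plaquedose.mc` — a voxelized photon Monte Carlo (numba): exact
  voxel-boundary ray marching with track-length collision-kerma scoring,
  photoelectric / Klein-Nishina Compton / form-factor Rayleigh physics on
  1–40 keV, batch statistical uncertainties.
- `plaquedose.phantom` — synthetic phantoms: the 10 cm water scoring box
  and an analytic voxel eye (globe, sclera, lens, optic nerve, dome tumor)
  at 0.39 × 0.39 × 0.4 mm resolution, medial or juxtapapillary tumor.
- `plaquedose.dvh` — the planning surface: prescription normalisation,
  peripheral comparison point, the ±5% matching criterion, loading search,
  cumulative DVHs and D_x% metrics.
- `plaquedose.pipeline` / `plaquedose.cli` — named study cases, engine
  calibration, artifact output, and a `plaquedose` command-line tool.
- `analysis/01..03_*.py` — the study drivers: water-box profiles,
  comparison-point table, eye-phantom DVH analysis.

## Worked example

```python
from plaquedose import (build_coms_plaque, assign_loading,
                        load_default_dataset, dose_rate_single)

dataset = load_default_dataset()
plaque = build_coms_plaque(16)
# clinical non-uniform loading: group 1 = 4.4 U, group 2 = 2.14 U, group 3 = 1.02 U
seeds = assign_loading(plaque, {1: 4.4, 2: 2.14, 3: 1.02})
presc = sum(dose_rate_single(s, (0, 0, 5.0), dataset) for s in seeds)
comp = sum(dose_rate_single(s, (7.7, 0, 3.0), dataset) for s in seeds)
print(f"prescription point : {presc:.2f} cGy/h")
print(f"comparison point   : {100 * comp / presc:.1f} % of prescription")
```

prints

```
prescription point : 56.22 cGy/h
comparison point   : 99.7 % of prescription
```

i.e. the non-uniform loading reproduces the prescription dose at the
peripheral comparison point on the inner sclera — the plan "matches" the
uniform COMS distribution within the clinical ±5% criterion.  Running the
same plan through the full Monte Carlo (`analysis/02_comparison_points.py`)
drops that point to roughly 82% of the prescription: the silastic and the gold rim
attenuate what the water formalism cannot see.

The study drivers print their own summaries and write CSV tables under
`results/`:

```sh
python analysis/01_water_profiles.py      # Fig-2/3-style profiles
python analysis/02_comparison_points.py   # three-engine point table
python analysis/03_eye_dvh.py             # eye-phantom cDVHs and D-metrics
```

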