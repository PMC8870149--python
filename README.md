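# gliomech

Biomechanically coupled simulation of brain-tumor growth and nanoparticle
drug delivery on heterogeneous, elastography-like stiffness maps.

A growing glioma, confined by the surrounding brain, accumulates
compressive solid stress. `gliomech` models the downstream cascade of that
stress and its feedback on growth:

* **Synthetic virtual patients** — seed-reproducible storage/loss-modulus
  volumes (stand-ins for MR-elastography maps, including an intratumoral
  stiffness texture) and DTI-like cell-diffusivity tensor volumes.
* **Constitutive inversion** — storage/loss moduli at the driving
  frequency are inverted in closed form to an elastic shear modulus and a
  relaxation time.
* **Stress-regulated growth** — multiplicative growth kinematics
  (F = Fe·Fg) with an oxygen-limited Michaelis–Menten growth rate,
  partitioned across the principal axes by a normalized exponential of the
  normal stresses, so growth is steered away from the most compressed
  directions (anisotropy degree A; A = 0 is isotropic).
* **Finite-strain mechanics** — compressible neo-Hookean equilibrium on a
  spherified-cube hexahedral mesh with a mean-dilatation (B-bar)
  formulation, loaded by growth and by the interstitial-pressure gradient.
* **Vessel compression** — compressive bulk stress exponentially narrows
  microvessels and reduces the functional vascular density S_v.
* **Interstitial fluid pressure** — a steady source/sink Darcy problem:
  plasma filtration from the vasculature against lymphatic drainage
  (absent inside the tumor), producing the classic elevated tumor-core
  IFP with a sharp rim gradient.
* **Oxygen and cells** — quasi-steady oxygen supplied by the (compressed)
  vasculature and consumed by cells; cell density grows and diffuses
  along the DTI tensor field.
* **Hindered drug transport** — pore-level hindrance factors for a
  nanoparticle in a cylindrical vessel-wall pore (diffusive and
  convective hindrance, reflection coefficient), a Starling transvascular
  source driven by a decaying plasma bolus, and interstitial
  diffusion/convection with binding and cellular internalization.

All couplings run in a single loop: growth → mechanics → vessel
compression → IFP/oxygen → growth, with the drug bolus delivered into the
grown, stressed tumor. See `docs/methods.md` for equations, parameter
tables, verification oracles, and limitations.

## Worked example

Generate a virtual patient and run the default 43-day coupled course
(5 mm tumor seed in a 50 mm host sphere, isotropic growth, 2-day drug
window at the end):

```sh
gliomech generate-patient --out-dir patient7 --seed 7
gliomech run --out-dir run7 --seed 7
gliomech report run7
```

which prints:

```text
wrote virtual patient (seed 7) to patient7
wrote series.csv, summary.json, config.yaml to run7
final tumor volume 1476.9 mm³, mean bulk stress -765 Pa
run directory: run7
  time_days                                          43
  tumor_volume_mm3                                 1477
  tumor_bulk_stress_mean_pa                      -765.1
  tumor_bulk_stress_sd_pa                          2230
  tumor_sv_mean_per_mm                           0.3835
  tumor_sv_sd_per_mm                             0.2385
  tumor_p_i_mean_pa                                1997
  tumor_p_i_sd_pa                                 1.815
  tumor_sphericity                               0.9598
  tumor_shape_asymmetry                         0.07338
  tumor_c_int_mean                              0.08899
  tumor_c_int_sd                                0.01624
  tumor_c_int_asymmetry                          0.1176
  tumor_c_int_fraction_above_half_mean           0.9606
  tumor volume grew 2.92x over 43.0 days (44 checkpoints)
```

Reading the numbers: the tumor roughly triples in volume, its mean solid
stress swings from an early filtration-driven tensile transient to a net
compression of about −0.8 kPa (several kPa in the core), which cuts the
functional vascular density nearly in half (0.70 → 0.38 mm⁻¹) and
collapses core oxygen, while IFP plateaus within a fraction of a percent
of the 2 kPa microvascular pressure. Internalized drug after the 2-day
bolus averages ≈ 0.09 of the injected plasma concentration, delivered
mostly to the better-perfused rim.

Stress-directed growth: rerunning with `--anisotropy 25` (and 50) makes
the tumor grow preferentially along its least-compressed axes in the
heterogeneous stiffness environment. At the default patient seed with
1-day steps (the configuration the acceptance tests use), final
sphericity drops from 0.967 (A = 0) to 0.955 (A = 25) to 0.949 (A = 50)
at the same final volume scale, and the A = 25 and A = 50 shapes overlap
each other more (Dice 0.990) than A = 0 overlaps A = 25 (Dice 0.978).

## Reproduction

Everything is deterministic given a seed: the virtual-patient fields use
`patient.seed` (stiffness, intratumoral texture, and DTI use fixed seed
offsets), and the solvers contain no stochastic elements.

`scripts/acceptance.py` runs the headline numerical experiments for one
patient seed and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out acceptance_seed1.json
```

This produces (in roughly 10 minutes on one core):

* a heterogeneous vs constant-modulus-control coupled pair (30 days,
  2-day drug window) with tumor stress, vascular-density, and drug
  statistics;
* a prescribed-growth frozen-state pair on a finer tumor-resolving mesh
  that isolates the stiffness → stress → vasculature → delivery chain
  (heterogeneous-to-control contrast in vascular-density spread and drug
  asymmetry);
* isotropic (A = 0) and stress-directed (A = 25) 43-day growth runs with
  final sphericities.

The acceptance tests in `tests/test_acceptance.py` verify, among others:
constitutive round trips to 1e-10; exact stress-free reference states;
3D stress and IFP profiles against independent 1D spherical solvers (2 %
L2 / 1 % L∞); the growth-partition identity ΣΓ = 1 to 1e-12; hindrance
factors against a 50-digit symbolic evaluation to 1e-10; exact discrete
mass conservation (< 1e-6 drift over 10³ steps); the two-regime IFP
plateau vs pore size; heterogeneity-contrast ratios; anisotropic shape
trends; and monotone delivery trends across particle sizes and pore
radii.

## Layout

* `src/gliomech/` — package: `config`, `fields` (virtual patients),
  `material`, `growth`, `meshing`, `mechanics`, `vasculature`,
  `transport`, `drug`, `oracles1d` (independent 1D verification solvers),
  `pipeline` (coupled loop + metrics), `cli`.
* `tests/` — unit, property (hypothesis), and acceptance tests;
  `tests/_oracles.py` holds the extended-precision hindrance oracle.
* `scripts/acceptance.py` — headline experiments, JSON output.
* `docs/methods.md` — model equations, parameters, numerics, limitations.
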