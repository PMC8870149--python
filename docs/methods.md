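# Methods

`gliomech` simulates the mechanical feedback loop of a growing brain tumor:
a stiff, confined tumor accumulates compressive solid stress; that stress
compresses microvessels; the loss of functional vasculature starves the
tumor of oxygen, elevates interstitial fluid pressure (IFP), and throttles
transvascular drug delivery; oxygen in turn limits growth; and the spatial
pattern of all of this is set by the heterogeneous stiffness of the
surrounding tissue, supplied as elastography-like voxel maps. This document
records the governing equations, the numerical choices, every default
parameter with its rationale, and the model's known limitations.

Unit system: lengths in mm, pressures in Pa, time in days (86 400 s), drug
and oxygen concentrations normalized to their vascular values. The "day" is
a simulation time unit; absolute rate calibrations are illustrative rather
than patient-specific.

## 1. Constitutive model and elastography inversion

Magnetic-resonance-elastography-like maps provide storage and loss moduli
(G', G'') at a driving frequency w. A single-relaxation-time solid gives

    G'  = G w^2 tm^2 / (1 + w^2 tm^2)
    G'' = G w tm     / (1 + w^2 tm^2)

inverted in closed form: w*tm = G'/G'' and G = G' + G''^2/G'
(`material.reconstruct_shear_modulus`). Only the elastic branch G enters
the mechanics; tm is computed and stored but unused.

The solid is compressible neo-Hookean with an isochoric split,

    W(Fe) = G/2 (I1_bar - 3) + k/2 (Je - 1)^2,
    I1_bar = Je^(-2/3) tr(Fe^T Fe),

so the reference state is exactly stress-free. The variant without the
isochoric correction (shear term in the raw first invariant) is available
behind `material.isochoric = False`; it carries a spurious reference-state
stress and is kept only for comparison. Cauchy stress is
sigma_s = Je^-1 Fe (dW/dFe)^T; its trace ("bulk stress", negative =
compression) drives vessel compression and growth anisotropy.

## 2. Growth kinetics

Deformation is decomposed multiplicatively, F = Fe Fg, with a diagonal
growth tensor Fg = diag(lg1, lg2, lg3) per element. The mass growth rate
is Michaelis-Menten in oxygen and proportional to the local cell density,

    r_g = k1 * c_ox/(k2 + c_ox) * T_cel .

Growth is distributed across the three axes by a normalized exponential of
the normal stresses sigma_aa (less compressive axes grow more),

    Gamma_a = exp(A sigma_aa / k) / sum_b exp(A sigma_bb / k),
    sum_a Gamma_a = 1,

where A is the anisotropy degree (0 = isotropic) and k the bulk modulus.
The implementation subtracts the maximum argument before exponentiating,
so the normalization holds to 1e-12 even for extreme stress contrasts.
Stretches update by the exact exponential integrator
lg_a <- lg_a * exp(Gamma_a r_g dt), which makes det Fg evolve exactly as
exp(r_g t) when A = 0.

## 3. Mechanical equilibrium

Quasi-static balance div(sigma_s) = grad(p_i) is solved on a
spherified-cube hexahedral mesh (concentric tumor + host shells) by a
displacement finite-element method with 2x2x2 Gauss quadrature and
mean-dilatation (B-bar) treatment of the volumetric term to avoid locking
at k/G >> 1. The nonlinear system is solved by modified Newton with
growth-increment ramping and reuse of the factorized tangent across steps
(warm starts come from the previous step). The IFP load enters as a nodal
pressure-gradient body force; a spatially uniform p_i therefore produces
zero displacement, which the tests verify. Outer boundary: fixed
(skull-scale confinement) for pipeline runs; a traction-free option exists
and is used by the compatible-growth tests.

## 4. Vessel compression and functional vascular density

Compressive bulk stress narrows microvessels,

    d/d0 = exp(-ln 2 * max(0, -sigma_bulk)/sigma_half),

i.e. halving the diameter ratio per sigma_half of compression, clipped at
tensile stress; the functional vascular density is S_v = S_v0 * d/d0. The
law is pluggable (`vasculature.vessel_compression(law=...)`).

## 5. Interstitial fluid pressure and Darcy flow

Steady IFP solves

    -div(k_th grad p_i) = L_p S_v (p_v - p_i) - L_pl S_vl (p_i - p_vl),

with lymphatic drainage only outside the tumor, far-field pressure pinned
to gauge zero, and the vessel-wall filtration conductivity L_p derived
from pore geometry (section 7). In the leaky-vessel regime the tumor core
plateaus within a fraction of a percent of p_v, with a boundary layer at
the rim whose physical width sqrt(k_th/(L_p S_v)) is tens of micrometres —
far below element size, so the discrete rim transition is mesh-limited
(this is the physically expected "uniformly elevated IFP" regime). The
interstitial velocity is v_f = -k_th grad p_i.

## 6. Oxygen and cells

Oxygen is quasi-steady (Picard iteration on the Michaelis uptake):

    div(D_ox grad c_ox) + Per_ox S_v (c_iox - c_ox)
        - A_ox T c_ox/(c_ox + k_ox) = 0,

convection neglected (interstitial Peclet numbers are tiny). Cells follow
dT/dt = div(D_T grad T) + r_g T with the DTI-like tensor field D_T,
advanced by an exact pointwise exponential reaction and backward-Euler
diffusion.

## 7. Hindered transvascular and interstitial drug transport

For a particle of radius r_d in a cylindrical pore of radius r0
(lambda = r_d/r0), the partition factor is F = (1 - lambda)^2, and the
hydrodynamic resistances K_t, K_s are evaluated from the published
seven-coefficient asymptotic series (singular lead
(9 pi^2 sqrt(2)/4)(1-lambda)^(-5/2) plus polynomial). The diffusive and
convective hindrance factors and the reflection coefficient are

    H = 6 pi F / K_t,
    w = F (2 - F) K_s / (2 K_t),
    sigma_f = 1 - w.

Because the published coefficients are rounded, the lambda -> 0 limits
hold to ~1e-6 (not machine precision); the lambda = 1 limit is exact. The
test suite checks the implementation against an independent 50-digit
sympy evaluation of the same series.

Vessel-wall coefficients: L_p = gamma r0^2 / (8 eta L_vw) (Poiseuille flow
through a pore-area fraction gamma of a wall of thickness L_vw), and
Per = gamma H D0 / L_vw with the Stokes-Einstein free diffusivity
D0 = k_B T / (6 pi eta r_d). The transvascular drug source is Starling's
approximation

    Q = Per S_v (C_iv - c_f) + L_p S_v (p_v - p_i)(1 - sigma_f) C_iv,

with bolus plasma concentration C_iv = exp(-(t - t0)/k_d). Free drug c_f
diffuses (D_f = 0.3 D0, a tissue tortuosity factor), convects with v_f,
and exchanges with bound (c_b) and internalized (c_int) pools through
pairwise transfers (binding k_on c_e Phi, unbinding k_off,
internalization k_int), sub-stepped so no pool is overdrawn; the sum
c_f + c_b + c_int is conserved exactly by construction in a closed system.

## 8. Synthetic virtual patients

Real patient elastography/DTI volumes are replaced by seed-reproducible
synthetic fields: white Gaussian noise smoothed with a Gaussian kernel of
width `correlation_length`, affinely rescaled to a target mean/SD, clipped
at a positive floor; the loss modulus is a fixed fraction of storage. DTI
tensors are axisymmetric about a smoothly varying unit director with the
trace pinned to 3x the base diffusivity (symmetric positive definite by
construction). A separate patient-tumor stiffness map is generated on a
dedicated 1 mm grid and embedded into the spherical tumor seed by an
affine squeeze of its bounding box onto the seed's circumscribing cube, so
the tumor interior is itself heterogeneous. The constant-modulus control
replaces the stiffness in each region (tumor / host) by its
volume-weighted average, which matches the region means by construction.

Caveats: these are stationary Gaussian textures — they reproduce the
amplitude and correlation scale of tissue stiffness maps but none of
their anatomy (no gray/white structure, no ventricles, no skull
geometry); all distributional defaults below are assumptions, not fits.

## 9. Numerical choices

* **All scalar transport on trilinear hexahedra.** An earlier prototype
  assembled transport on a 6-tet split of the hex mesh; the split produces
  sliver tets (quality ratio ~3e-5 on spherified-cube geometry) whose
  volumes change sign under smooth deformations that the hexes tolerate.
  Trilinear hex quadrature keeps positive Jacobians wherever the mechanics
  converges, and the stiffness/convection matrices have exact zero
  row/column sums, giving discrete conservation to round-off.
* **Row-sum lumped mass** for all transient solves (positivity, cheap
  inversion, exact conservation with the matrices above).
* **Sharp-interface reaction lumping.** The IFP reaction coefficients are
  integrated per element and lumped to vertices, so the tumor/host
  coefficient jump is not smeared by nodal averaging.
* **Element-wise exact reactions.** Cell growth uses the exact exponential
  update; drug binding uses pairwise conservative transfers; oxygen uses a
  semi-implicit pointwise update that preserves [0, c_iox].
* **Interior tumor statistics.** The interface-adjacent element layer
  carries an unresolved stress boundary layer (its within-shell relative
  spread stays 0.13-0.21 across 3/3 -> 5/5 shell refinements while
  interior layers converge below 0.08); region statistics that feed
  sensitive comparisons therefore use `interior_tumor_mask`, which peels
  one element ring off the tumor surface.
* **Problem sizes.** Default runs use 3 tumor + 3 host shells (13^3 node
  lattice) — deliberately coarse so a full 43-day course runs in a few
  minutes on one core. Comparisons that need tumor resolution (the
  heterogeneity-contrast experiments) use 6 tumor shells. These are this
  package's own runtime choices; convergence of the radial profiles is
  verified against independent 1D solvers (section 10).

## 10. Verification oracles

Two one-dimensional spherically symmetric solvers, sharing no code with
the 3D path, serve as references: (i) an energy-minimizing
finite-difference solver for confined growth of a tumor sphere inside a
host shell (principal-stretch re-derivation of the constitutive law,
damped Newton on a graded radial grid), matched by the 3D stress profiles
within 2 % (volume-weighted L2); (ii) a conservative tridiagonal
reaction-diffusion solver for the radial IFP profile, matched within 1 %
(L-infinity). The hindrance factors are checked against a 50-digit sympy
evaluation of the same published series.

## 11. Parameters

Geometry and mesh (`geometry`):

| parameter | default | units | rationale |
|---|---|---|---|
| tumor_radius | 5 | mm | typical seed lesion scale |
| host_radius | 50 | mm | skull-scale confinement radius |
| n_tumor_shells / n_host_shells | 3 / 3 | - | coarse default (runtime, section 9) |
| grading_ratio | 1.9 | - | geometric host-shell grading |

Virtual patient (`patient`):

| parameter | default | units | rationale |
|---|---|---|---|
| mre_frequency_hz | 30 | Hz | typical brain elastography driving frequency |
| host_storage_mean / sd | 1500 / 400 | Pa | brain-tissue storage modulus scale and spread at tens of Hz |
| tumor_storage / tumor_storage_sd | 1100 / 290 | Pa | glioma slightly softer than brain; similar fractional spread |
| correlation_length | 3 | mm | gyral-scale stiffness variation; must be below the tumor diameter for intratumoral heterogeneity to exist |
| loss_ratio | 0.4 | - | loss/storage ratio typical of brain tissue |
| clip_floor | 100 | Pa | positivity floor |
| voxel_spacing | 2 | mm | elastography-like resolution |
| dti_base | 0.05 | mm^2/day | glioma-cell motility scale |
| dti_anisotropy | 0.3 | - | moderate white-matter-like anisotropy |

Material and growth (`material`, `growth`):

| parameter | default | units | rationale |
|---|---|---|---|
| k_bulk | 20 000 | Pa | near-incompressible, k/G ~ 20 (uniform assumption; section 12) |
| k1 | 0.06 | 1/day | ~12-day volume doubling at full oxygen |
| k2 | 0.1 | - | growth half-saturation well below vascular oxygen |
| rho_cell | 0.012 | 1/day | slow host-side proliferation |
| anisotropy A | 0 | - | isotropic unless studying stress-directed growth (25, 50) |
| dt / duration | 0.5 / 43 | day | resolves the growth dynamics; ~6-week course |

Vasculature and fluid (`vasculature`, `fluid`):

| parameter | default | units | rationale |
|---|---|---|---|
| s_v0 | 0.7 | 1/mm | 70 cm^-1 functional vascular density |
| sigma_half | 1000 | Pa | kPa-scale stress halves vessel diameter |
| k_th | 3.1e-8 | mm^2/(Pa s) | tumor interstitium hydraulic conductivity |
| p_v | 2000 | Pa | ~15 mmHg microvascular pressure |
| lymph_coeff | 1e-9 | 1/(Pa s) | host lymphatic drainage; absent in tumor |

Oxygen and drug (`oxygen`, `drug`):

| parameter | default | units | rationale |
|---|---|---|---|
| d_ox | 172.8 | mm^2/day | 2e-3 mm^2/s oxygen diffusivity |
| per_ox | 30 | mm/day | vascular wall permeability to oxygen |
| a_ox / k_ox | 40 / 0.15 | 1/day, - | uptake producing a hypoxic core at collapsed S_v |
| drug_radius_nm | 70 | nm | mid-size nanoparticle |
| pore_radius_nm | 200 | nm | leaky tumor vessel-wall pore |
| gamma | 0.05 | - | pore area fraction of the wall |
| eta_pa_s | 3e-3 | Pa s | plasma viscosity |
| l_vw_um | 5 | um | vessel-wall thickness |
| d_f_factor | 0.3 | - | interstitial tortuosity reduction of D0 |
| kon_ce_phi / k_off / k_int | 100 / 10 / 10 | 1/day | binding-dominated uptake with slow release |
| k_d | 1 | day | bolus circulation decay time |
| t_injection / t_readout | 41 / 43 | day | 2-day delivery window on the grown tumor |
| dt_minutes | 1 | min | resolves the bolus transient |

## 12. Limitations

* **Early-time tensile transient.** With the div(sigma_s) = grad(p_i)
  coupling, the solid stress starts near +p_i I (~ +2 kPa trace) before
  growth stress accumulates, crossing into net compression after roughly
  two weeks of growth. Physically a poroelastic unloaded state would be
  handled by an initial-stress calibration; here the transient is
  documented, and the vessel-compression clip at tensile stress makes S_v
  insensitive to it.
* **Bulk stress carries no direct shear-modulus signature.** With the
  isochoric energy the deviatoric Cauchy stress is exactly traceless, so
  local stiffness reaches the bulk stress only through equilibrium
  redistribution of the volumetric strain; k_bulk is a uniform assumption.
* **Coupled-run angular discretization noise.** On the coarse
  spherified-cube meshes, angular error in the transport fields feeds the
  growth stretches over tens of steps, and sigma_bulk ~ 3k(Je - 1)
  amplifies a ~1 % volumetric incompatibility into hundreds of Pa. In a
  control run that should be radially symmetric this noise dominates the
  spatial SD of S_v and the asymmetry metric of the drug field. For that
  reason the heterogeneity-contrast acceptance experiments are run on
  prescribed-growth frozen states (uniform tumor growth stretch on a
  tumor-resolving mesh), where the control is radially symmetric up to
  solver error and the measured contrast isolates the
  stiffness -> stress -> vasculature -> delivery chain; the coupled-run
  statistics are still computed and reported by `scripts/acceptance.py`,
  without thresholds, for transparency. At the mesh sizes affordable on
  one core, the coupled-run S_v SD ratio between heterogeneous and
  control arms is ~1.0-1.2 and the drug-asymmetry ratio ~1.2-2.6, both
  noise-limited.
* **Geometry.** Concentric spheres with a fixed outer boundary; no
  anatomy, no ventricles, no falx. Sphericity and Dice metrics are
  computed on the voxelized deformed tumor surface of a coarse mesh and
  should be compared only within one mesh family.
* **No angiogenesis, necrosis, or matrix remodeling;** vasculature only
  loses function under stress and never recovers.
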