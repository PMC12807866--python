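# Methods

## The model

`lumenmorph` simulates an organoid cross-section as a collection of scalar
phase fields on a regular 2D lattice: one field u_m(x,t) ∈ [0, 1] per cell
and a single shared lumen field w(x,t).  A field value near 1 means "this
point is inside the object"; interfaces are diffuse, with a logistic
equilibrium profile of scale ε/√(2W).  All mechanics derive from one free
energy

    F = Σ_m ∫ (ε²/2)|∇u_m|² + W u_m²(1−u_m)² dx
      + ∫ (ε²/2)|∇w|² + W_w w²(1−w)² dx
      + Σ_m α (V_target,m(t) − V_m(t))²
      + (β/2) ∫ H_c² − Σ_m h(u_m)² dx            H_c = Σ_m h(u_m)
      + β_w ∫ H_c h(w) dx
      − ξ ∫ h(w) dx

with h(u) = u²(3 − 2u) the smooth volume interpolant and
V_m = ∫ h(u_m) dx².  The terms are, in order: cell interface tension
(line tension σ = ε√(2W)/6), lumen interface tension (σ_w = ε√(2W_w)/6),
a quadratic volume constraint that acts as the cell's internal pressure,
cell–cell and cell–lumen exclusion (fields penalised for overlapping),
and the lumen osmotic pressure ξ, which performs work −ξ per unit of
lumen volume and is one constant shared by every lumen of the organoid.
Two optional adhesion couplings (a cell–cell cross-gradient term and a
cell–lumen interface attraction) are implemented and reported in the
energy breakdown but default to zero; cohesion in the default
configuration comes from exclusion plus the inflating lumen pressing the
cells into a shell.

Dynamics are non-conserved (Allen–Cahn) gradient flow
∂u/∂t = −M δF/δu, integrated with explicit Euler on per-cell bounding
boxes (cells are compact) and the full domain for the lumen field.
Boundaries are zero-flux (mirror); runs abort if the organoid reaches a
4-site margin.  Two numerical safeguards keep the explicit scheme robust
during crowded division cascades: field values are projected onto
[−0.02, 1.02] after each update, and the volume-constraint driving force
2α(V_target − V) is saturated at ±1.2, so a freshly carved cell cannot
out-push exclusion and interpenetrate its neighbours.

### Growth, division, micro-lumina

Each cell's target volume obeys τ_V dV_target/dt = V̄ − V_target, applied
as the exact exponential integrator (relative error < 1e−9 for any step).
A cell divides the instant its actual volume reaches V_d; there is no
refractory period.  The cleavage plane passes through the centroid,
normal to the long axis of the supra-0.5 region (a Hertwig-rule proxy for
spindle positioning; the policy is a plain function and can be replaced).
Nearly isotropic cells draw a random axis from the run's seeded RNG.
Daughter target volumes reset to max(v_daughter, V_d/2), multiplied by a
±5% seeded jitter that desynchronises lineages the way natural
cell-cycle variability would; without it, all cells of a generation divide
in the same time step and the transient crowding is unphysical.

At the end of every division a micro-lumen of area `micro_lumen_size` is
seeded at the parent centroid (the abscission point).  The seed's disc
radius is calibrated so its integrated h-measure equals the configured
area, and the cell fields are locally suppressed underneath it —
abscission displaces membrane, creating the cavity; the cells recover the
lost volume through their volume constraint.

### Permeability: the sealed-epithelium rule

Osmotic pressure can only build across an epithelium.  The lumen drive ξ
acts everywhere, but lumen fluid outside the *sealed region* — the
morphological closing of the cell mask (which bridges inter-cell clefts
and small shell gaps, up to about twice the 8-pixel closing radius) plus
every cavity that closed shell encloses — decays at rate 0.5 per time
unit.  A micro-lumen cradled in a cell cleft is sealed; a lumen bulging
through a transient shell opening loses its exposed part but keeps its
cavity; fluid escaping into the open medium drains away.  This rule is
what prevents the unphysical runaway of a free lumen droplet (constant
pressure always beats tension at large radius) while letting enclosed
lumina grow.

### Pressure read-out

`estimate_insilico_pressure` reports, per connected lumen, the mechanical
work the surrounding material extracts per unit of cavity growth:
ΔP = dF_rest/dA under a small virtual outward dilation of that lumen's
boundary, where F_rest is the free energy without the −ξV term.  For a
bare circular lumen this reduces to the Laplace law σ_w/R (verified in
the tests); with an enclosing shell it additionally transmits the
exclusion and cell-compression stresses.  At force balance the estimate
equals the applied ξ, which is why the inferred hydrostatic pressure of
matched-size lumina is linear in ξ (`pressure_xi_calibration` measures
the slope; R² ≈ 0.999 in the shipped configuration).  Lumina whose
boundary is mostly exposed to the medium are flagged low-confidence.

## Parameters

Published model values:

| parameter | value | meaning |
|---|---|---|
| α | 1.0 | volume-constraint strength |
| V̄ | 3.0 | asymptotic target volume |
| micro_lumen_size | 0.7 | area of the nascent lumen seed |
| ξ | 0.10–0.32 | lumen osmotic pressure (swept) |
| τ_V | 1–90 | target-volume convergence time (swept) |

Calibration constants (not printed in any source; chosen once so that the
four qualitative corner behaviours of the ξ × τ_V diagram appear —
many small lumina at fast cycling/low ξ, a single inflated lumen at slow
cycling/high ξ — and kept fixed thereafter):

| parameter | value | note |
|---|---|---|
| V_d | 2.0 | division volume; inter-division time ≈ 0.69·τ_V |
| dx, nx | 0.11, 128 | lattice; a V̄-sized cell spans ~9 sites radius |
| dt | 0.01 | ≈ 25% of the diffusive stability bound |
| ε | 0.22 | interface parameter (2 lattice sites) |
| W, W_w | 1.0, 0.15 | cell and lumen well depths; σ = 0.052, σ_w = 0.020 |
| β, β_w | 4.0, 0.8 | cell–cell and cell–lumen exclusion |
| M, M_w | 1.0, 0.3 | mobilities; the slower lumen keeps coarsening slower than the division cadence, which is what preserves branched morphologies under ongoing division |
| leak rate, closing radius | 0.5, 8 px | sealed-epithelium rule (above) |

All quantities are dimensionless simulation units; converting to physical
units requires an external length/time/pressure scale and is left to the
caller (occupancies, counts and the ξ ratio are scale-free).

## Study designs in the package

- **Phase diagram** (`sweep_phase_diagram`): one run per (τ_V, ξ, seed),
  default t_end = 60 with a capacity stop at 36 cells (the 128² domain's
  comfortable limit); phenotype = final snapshot.  The published grids
  τ_V ∈ {1, 10, …, 90} and ξ ∈ {0.10, 0.12, …, 0.32} (120 combinations)
  are the defaults; the end-to-end tests use the 3 × 3 sub-grid
  {10, 40, 90} × {0.10, 0.20, 0.30} with 5 seeds each and test the two
  orderings by pooled Spearman rank correlation.
- **Division arrest** (`arrest_experiment`): paired same-seed runs with
  and without an arrest count, at τ_V = 40, ξ = 0.12, on a roomier 160²
  lattice, t_end = 200.  The tests arrest at 16 cells (half the published
  32, matching the smaller domain).  Because the relaxed single lumen
  slowly cycles between inflation and reseal, paired comparisons use the
  mean occupancy over the final quarter of the common time window and the
  lumen count at the common end time.
- **ΔP–ξ calibration** (`pressure_xi_calibration`): an 8-cell
  non-dividing shell with a central seed, run until the lumen reaches a
  fixed area (default 8.0) so the geometric Laplace contribution is
  matched across ξ, then read with the virtual-work estimator.

## The synthetic-data generators

Every generator in `lumenmorph.fixtures` is the forward model of exactly
one inference path, with its ground truth attached:

- `gen_brownian_tracks`: 3D Gaussian random walks with per-axis increment
  variance 2D·dt; D either given or derived from (μ, a, T) by
  Stokes–Einstein.  Optional static Gaussian localisation noise, off by
  default.  What it does **not** emulate: confinement by the lumen
  boundary, particle polydispersity within a track, tracking/linking
  errors, anisotropic localisation error (worse along z in real
  spinning-disk stacks).  Passing recovery tests therefore validate the
  MSD → D → μ arithmetic and the filters, not robustness to those
  real-data artefacts.
- `gen_ablation_record`: integrates dV/dt = −πr_c⁴ΔP/(8μL) with constant
  ΔP (default) or a Laplace-coupled decaying mode, plus optional Gaussian
  volume noise.  It does not model conduit closure over time or
  segmentation bias in the volume series.
- `gen_label_volume` / `gen_duct_filter_scenario`: rasterised spheres and
  ellipsoids with closed-form volume/surface ground truth (ellipsoid
  surface via the Knud Thomsen approximation, error < 1.1%); voxelisation
  error at 1 µm voxels is ~2% for a 10 µm sphere, which bounds what the
  morphometric tests can assert.
- `gen_intensity_samples`: Gaussian mixtures for the KDE-threshold path.

## Numerical choices and edge cases

- KDE intersection threshold: Gaussian KDEs with bandwidth
  h = 1.06 σ n^(−1/5), difference scanned ascending on 512 grid points
  spanning the pooled range, zero crossing linearly interpolated; no sign
  change raises a dedicated error.  The scan is symmetric in the sample
  order.
- Duct-label filter: the three steps run strictly in order (edge removal,
  337 µm³ threshold, strictly-below-median selection); the median is
  computed per image over the post-threshold labels, the only
  self-contained reading of the rule.
- Tile density: tiles anchor at the region bounding-box origin
  (configurable anchoring was considered and rejected as an untestable
  degree of freedom); a tile qualifies at ≥ 50% in-region volume; label
  membership is by centroid.
- Flow-rate fits use ordinary least squares on the post-cut window
  (optionally truncated); a positive slope beyond twice its standard
  error is reported as "no outflow" with ΔP = 0 — the ablation method
  only senses expulsion, never negative pressure.
- MSD fits use the first 25% of lags (at least 3) with an intercept, so
  static localisation noise does not bias the slope; D = slope/6.
  The track-length filter is strict (> 20 frames).
- Division of a cell whose supra-0.5 region has vanished (transiently
  over-compressed) is deferred to a later step rather than forced.
- `run` flushes partial metrics and flags the failure mode when a run
  aborts (margin contact, volume runaway, non-finite fields), so sweeps
  continue past individual failures.

## Known limitations

- 2D only; no cell death or rearrangement; no explicit ion transport —
  ξ is a phenomenological stand-in for everything the epithelium's
  permeability does to lumen osmolarity.
- The free-energy coefficients other than α are calibration constants of
  this implementation, not measured quantities; conclusions should rest
  on the orderings and ratios the tests assert, which are robust to the
  calibration, not on absolute occupancies or pressures in simulation
  units.
- The sealed-epithelium leak rule is algorithmic (morphological closing),
  not variational; energy descent is exact only at ξ = 0 or for fully
  sealed states, and the descent tests run in that regime.
- At desk scale (≤ 40 cells) the relaxed single lumen of an arrested
  organoid undergoes slow inflation/reseal cycles; time-point phenotypes
  of such states are therefore evaluated as short time-window means.
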