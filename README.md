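# lumenmorph

Phase-field simulation and quantitative analysis of lumen morphogenesis in
pancreatic organoids.

Pancreatic organoids grown from embryonic progenitors develop either a
single large spherical lumen or a network of narrow, interconnected lumina.
`lumenmorph` implements a 2D multicellular phase-field model in which this
dichotomy emerges from the balance of two control parameters: the lumen
osmotic pressure **ξ** (set by how well the epithelium retains solutes) and
the cell-cycle duration knob **τ_V**.  Fast division at low pressure keeps
seeding micro-lumina faster than they can fuse — a branching phenotype;
slow division at high pressure lets a single lumen inflate and coarsen —
a spherical phenotype.  The package also provides the measurement layer
used to compare such simulations with experiments: lumen counting and
occupancy, sphericity and other morphometrics, Hagen–Poiseuille inference
of lumen hydrostatic pressure from laser-ablation records, and
Stokes–Einstein viscosimetry from 3D particle tracking.  It is aimed at
researchers in epithelial mechanics and organoid biology who want a
reproducible, scriptable version of this modelling-plus-quantification
workflow.

## Model

Each cell *m* is a smooth field u_m(x) ∈ [0, 1] and all lumina share one
field w(x); mechanics are a free energy

    F = Σ_m ∫ (ε²/2)|∇u_m|² + W u_m²(1−u_m)² dx        interface tension
      + Σ_m α (V_target,m(t) − V_m(t))²                 volume constraint
      + exclusion and adhesion couplings between fields
      − ξ · V_lumen                                      osmotic pressure

relaxed by Allen–Cahn gradient flow (explicit Euler, zero-flux
boundaries).  Each cell's target volume follows

    τ_V dV_target,m/dt = V̄ − V_target,m(t)

(exponential approach to V̄ = 3.0, integrated exactly), and a cell divides
the moment its actual volume reaches the division volume V_d.  Every
division seeds a micro-lumen of fixed size 0.7 at the abscission point.
Osmotic pressure only builds across a sealed epithelium: lumen fluid that
escapes the cell shell drains back into the medium.  See
`docs/methods.md` for the complete description, all default parameters and
their provenance.

The measurement layer implements, among others:

- sphericity Ψ = (36πV²)^(1/3)/SA (1 for a sphere),
- 2D/3D lumen occupancy (% of organoid volume),
- Hagen–Poiseuille ΔP = 8μLQ/(πr_c⁴) from post-ablation volume decay,
- Stokes–Einstein μ = k_BT/(6πaD) from MSD-fitted diffusion coefficients
  with the track-length (> 20 frames) and linear-fit (R² > 0.75) filters,
- the three-step duct-label filter (edge removal, 337 µm³ threshold,
  below-median "isolated" selection) and its volumetric tile density.

## Worked example

Estimate the lumen fluid viscosity from synthetic tracer particles, use it
to infer the hydrostatic pressure of a lumen from an ablation record, and
place the two organoid phenotypes on the ξ × τ_V diagram:

```python
from lumenmorph import biophysics as bp
from lumenmorph import insilico_quant as iq
from lumenmorph.fixtures import gen_ablation_record, gen_brownian_tracks

ts, truth = gen_brownian_tracks(n_particles=100, frame_dt_s=1.0,
                                n_frames=500, viscosity_pa_s=2.1e-3,
                                radius_um=0.5, temperature_k=310.0, seed=0)
visc = bp.viscosity_pipeline(ts)
print(f"median lumen viscosity: {visc['median_viscosity_pa_s']*1e3:.2f} mPa*s "
      f"({visc['n_surviving']} tracks pass the filters)")

rec, _ = gen_ablation_record(dp_true_pa=25.4,
                             viscosity_pa_s=visc["median_viscosity_pa_s"],
                             thickness_um=10.0, conduit_radius_um=1.0,
                             v0_um3=80_000.0, duration_s=60.0,
                             sample_dt_s=5.0, noise_sd_um3=800.0, seed=0)
est = bp.infer_pressure(rec)
print(f"inferred lumen pressure: {est.delta_p_pa:.1f} Pa "
      f"(fit R^2 = {est.diagnostics['r_squared']:.3f})")

placement = iq.map_invitro_to_phase_diagram(0.3, 0.14)
print(f"osmotic-pressure ratio, spherical vs branching: "
      f"{placement['xi_ratio']:.1f}")
```

prints

```
median lumen viscosity: 2.23 mPa*s (100 tracks pass the filters)
inferred lumen pressure: 26.5 Pa (fit R^2 = 0.995)
osmotic-pressure ratio, spherical vs branching: 2.1
```

The viscosity pipeline recovers the 2.1 mPa·s ground truth within its
sampling error from 500-frame tracks; the pressure inference recovers the
25.4 Pa ground truth from the noisy volume decay; and the placements of
spherical (ξ = 0.3) and branching (ξ = 0.14) organoids on the phase
diagram give an osmotic-pressure ratio of 2.1.

Simulations run from Python (`lumenmorph.sim_core.run`,
`lumenmorph.insilico_quant.sweep_phase_diagram`, `arrest_experiment`) or
from the CLI:

```bash
lumenmorph simulate --seed 3 --out out/run            # one organoid
lumenmorph sweep --tau-v 10 --tau-v 40 --xi 0.1 --xi 0.3 \
    --reps 3 --seed 1 --out out/sweep                 # phase diagram
lumenmorph arrest --arrest-count 16 --seed 1 --out out/arrest
```

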