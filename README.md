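# morphograd

Quantitative tools for studying how secreted morphogens — modelled on the
zebrafish Nodal ligands Squint (Sqt) and Cyclops (Cyc) — form concentration
gradients in embryonic tissue. The package re-implements, as tested and
reusable code, the computational analysis chain that connects single-molecule
fluorescence measurements to gradient shape:

1. **FCS/FCCS curve fitting** (`morphograd.correlation_models`) — evaluate and
   fit auto- and cross-correlation models (3D/2D, one/two components, triplet
   state) by Levenberg–Marquardt to extract particle numbers N, diffusion
   times τ_d and diffusion coefficients D = ω₀²/(4τ_d).
2. **Binding affinity and transport theory** (`morphograd.binding_affinity`) —
   dissociation constants from FCCS concentration regressions
   (C_g·C_r = K_d·C_gr) and ln K_d histograms; the quadratic mass-action bound
   fraction

       f_bound = (K_d+L_t+R_t)/(2L_t) − √((K_d+L_t+R_t)²/(4L_t²) − R_t/L_t),

   effective diffusion D_eff = D·f_free, and the gradient length

       λ = √(D/k) / √(R/K_d + 1).

3. **Hindered-diffusion simulation** (`morphograd.hindered_diffusion`) — 3D
   slab random walk among cylindrical cell obstacles (tortuosity) with
   optional Bernoulli binding; effective D recovered by fitting the
   point-source profile C(x,t) = exp(−x²/(4·D_eff·t)).
4. **1D gradient formation** (`morphograd.gradient_formation`) — particle
   simulation with continuous production, diffusion and first-order
   degradation, a closed-form reaction–diffusion oracle, exponential
   gradient fitting C(x) = A·exp(−x/λ) + C, and time-to-steady-state.
5. **Image profiling** (`morphograd.gradient_profiling`) and **clearance
   kinetics** (`morphograd.clearance_kinetics`) — intensity-vs-distance
   extraction from fluorescence images and exponential decay fitting of
   protein-abundance time courses.
6. **Synthetic data** (`morphograd.synthetic`) — generators for every input
   (noisy correlation curves, a Brownian photon-trace oracle, FCCS
   concentration sets, gradient images, decay series), each carrying its
   ground truth for round-trip recovery tests.

## Worked example

```python
from morphograd.binding_affinity import (
    bound_fraction, effective_diffusion, gradient_length)
from morphograd.hindered_diffusion import (
    SlabSimConfig, simulate_slab, concentration_profile, fit_gaussian_profile)

# A ligand with Kd = 60 nM at 100 nM total, in 40 uM of binding sites:
f = bound_fraction(kd=60, l_total=100, r_total=40_000)
print(f"bound fraction: {100*f:.2f}%")        # bound fraction: 99.85%

# Tortuosity-reduced D = 30 um^2/s and that free fraction give
print(effective_diffusion(30.0, 1 - f))       # 0.04504... um^2/s

# Gradient length from free D, clearance and receptor load:
print(gradient_length(60.0, 1e-4, 40_000, 60))   # 29.977... um

# Recover D_eff from a 5-s slab run among 10-um cells with 2-um gaps:
res = simulate_slab(SlabSimConfig(seed=1))
prof = concentration_profile(res.positions[:, 0], t=5.0, length_x=86.7)
print(fit_gaussian_profile(prof).d_eff)       # 36.95... um^2/s (input 60;
                                              # ~33.6 averaged over seeds)
```

The numbers mean: in a receptor-saturated tissue essentially all ligand is
bound at any instant (99.85%), so transport is slowed ~670-fold on top of the
~1.8-fold tortuosity reduction; diffusion, binding and clearance together set
an exponential gradient ~30 µm long for the slow-degrading ligand and ~19 µm
for the fast-degrading one.

A command-line interface mirrors the library:

```bash
morphograd equilibrium --kd 60 --ltot 100 --rtot 40000
morphograd fcs-fit --model 3d1c --input curve.csv --out fit.json
morphograd slab-sim --config slab.yaml --seed 7 --out run1/
morphograd gradient-sim --deff 0.09 --k 5e-4 --production 0.7 \
    --duration 60000 --seed 3 --out grad.csv
morphograd synth fccs --seed 2 --out data/
```

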