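# Methods

## Scope and model overview

The package treats morphogen gradient formation as the interplay of four
measurable quantities: the free diffusion coefficient D of the ligand, its
affinity for immobile binding sites (dissociation constant K_d and total
site concentration R), its first-order clearance rate k, and the geometry
of the tissue through which it moves. These combine in two stages:

- **Hindrance.** Cell bodies force diffusing molecules onto longer paths
  (tortuosity), reducing D by a factor bounded by 2 for extracellular
  geometries; transient binding to an excess of immobile sites reduces the
  mobile fraction to f_free ≈ K_d/(R + K_d), giving
  D_eff = D_tort · f_free under fast exchange.
- **Source–sink balance.** A localized source with uniform first-order
  clearance yields a steady exponential gradient with decay length
  λ = sqrt(D/k) / sqrt(R/K_d + 1) (equivalently sqrt(D_eff/k) with
  D_eff = D·f_free); on a finite reflecting domain of length L the profile
  is ∝ cosh((L−x)/λ).

## Correlation spectroscopy models

Fluorescence correlation spectroscopy (FCS) autocorrelation and
cross-correlation (FCCS) models share the structure
G(τ) = (1/N)·T(τ)·Σᵢ Fᵢ·Dᵢ(τ) + G_∞ with a triplet factor
T(τ) = 1 + F_trip/(1−F_trip)·e^(−τ/τ_trip) and per-component diffusion
factors; the 3D forms carry the axial term [1+(ω₀/z₀)²τ/τ_d]^(−1/2), the 2D
(membrane) and cross-correlation forms do not, and the cross-correlation
model carries no triplet term. The diffusion coefficient follows from the
fitted diffusion time as D = ω₀²/(4τ_d).

Fitting is Levenberg–Marquardt (lmfit backend, xtol = ftol = 1e−12),
weighted by per-point standard errors when available. Multi-start
refinement draws up to five log-normally jittered restarts from a fixed
sub-seed; a fit is accepted once two starts agree, guarding against local
minima in the two-component model. The triplet term is only varied when
the initial guess declares a nonzero triplet fraction: this prevents the
well-known exchange degeneracy between a free triplet term and the
diffusion decay when the data contain no photophysics. Triplet bounds
(F_trip ≤ 0.5, τ_trip ∈ [0.1, 100] µs) serve the same purpose. Two-component
results are reported with components sorted by ascending τ_d. Non-convergence
is reported through a `converged=False` result, never an exception; a
constant curve is an immediate fit failure.

The default observation volume for synthetic work is ω₀ = 0.25 µm,
z₀ = 1.25 µm (structure ratio 0.2, V_eff ≈ 0.43 fL) — typical confocal
values; instrument calibration is out of scope.

### Independent physical oracle

`brownian_photon_oracle` simulates particles diffusing through a 3D
Gaussian detection profile, records the summed intensity
I(t) = Σ exp(−2r²/ω₀² − 2z²/z₀²), and autocorrelates the trace by FFT with
unbiased lag normalization. It shares no code with the closed-form models,
so agreement of a model fit with the oracle (within the oracle's ~10–20%
sampling scatter at desk scale: ≤100 particles, ≤30 s of trace) checks the
entire model/fit chain against the underlying physics.

## Kd estimation

From ideal FCCS amplitudes, total particle numbers are N_g = 1/G_g(0),
N_r = 1/G_r(0) and the complex number is N_gr = G_x(0)/(G_g(0)·G_r(0));
free numbers follow by subtraction and concentrations by
C = N/(V_eff·N_A). No cross-talk or background corrections are applied —
a documented limitation, acceptable for synthetic and pre-corrected data.

Two estimators are provided, mirroring standard practice: (a) ordinary
least squares of C_g·C_r on C_gr with free intercept, slope = K_d; and (b) a
Gaussian fitted (least squares over Freedman–Diaconis bins, with a
Sturges fallback for near-degenerate samples and a moment fallback when
too few bins populate) to the histogram of per-sample ln K_d, reporting
exp(μ̂). On well-behaved data (CV of ln K_d below ~0.5) the two agree to
better than 20%; both are exposed because which one a given laboratory
reports is rarely stated.

## Slab simulation of hindered diffusion

Reference conditions: a 2 × 44 × 86.7 µm slab, 1000 particles released at
the x = 0 face, D = 60 µm²/s, 5 ms steps for 5 s; reflecting walls in x,
periodic in y and z. Cells are z-aligned cylinders of diameter 10 µm with
2 µm membrane-to-membrane gaps.

Geometry decisions (the stated slab width is not commensurate with the
12 µm lattice pitch, so some arrangement choice is unavoidable):

- Only whole cells are placed: as many rows as fit in the slab width
  without overlapping through the periodic boundary (three rows in 44 µm),
  centered. Wrapping a fourth row would merge two cells into one
  impassable block and push the hindrance far beyond the factor-2
  tortuosity bound for extracellular geometries.
- Alternate columns are staggered by half a pitch (close packing). An
  unstaggered grid leaves straight free channels spanning the whole slab,
  which dominate the recovered transport; staggered packing is both the
  realistic cell arrangement and free of that artifact. A square grid
  remains available via `lattice="square"`.
- The source wall sits in the middle of an intercellular gap (first column
  centered at radius + gap/2), so the wall acts as a mirror plane of the
  periodic medium and no cylinder crosses the source plane.
- Collisions use reject-and-stay: a step ending inside a cylinder is
  cancelled. Specular reflection is available (`collision_rule="reflect"`)
  but the reject rule is the default and the tested one.
- Binding uses quasi-equilibrium Bernoulli mobility: each particle moves
  in a given step with probability f_free. This reproduces
  D_eff = f_free·D exactly in distribution for step counts ≫ 1; explicit
  on/off kinetics are out of scope. For combined tortuosity-plus-binding
  predictions the tortuosity-reduced coefficient (D = 30 µm²/s) is used as
  input with obstacles off, because at f_free ≤ 0.1 the 5-s displacement
  (≲6 µm) is smaller than the 12 µm lattice period, so an explicit lattice
  would measure the near-source pore geometry rather than bulk transport.

The effective coefficient is recovered by fitting the max-normalized
binned profile (1 µm bins) with A·exp(−x²/(4·D_eff·t)). The amplitude
prefactor is free by default: with 1000 particles the peak bin holds only
~30 counts, and pinning the amplitude to that noisy bin biases D_eff low
by tens of percent and makes it strongly bin-width dependent; with the free
amplitude the estimator is unbiased and stable across bin widths
(`free_amplitude=False` restores the bare form). Under the reference
conditions the recovered values are D ≈ 59–61 µm²/s free, ≈ 33–35 µm²/s
with obstacles (reduction factor ≈ 1.7–1.8, always below 2), and
≈ 3 µm²/s at f_free = 0.1 on the tortuosity-reduced input.

## 1D gradient formation

Particles are injected at x = 0 as a Poisson process with the production
rate (0.07–0.7 s⁻¹ by default), take Gaussian steps with the effective
coefficient, are removed with probability 1 − e^(−k·dt) per step, and
reflect at both ends of a 200 µm domain. The time step is 1 s (per-step
displacement ≈ 0.42 µm at D_eff = 0.09 µm²/s), which resolves λ ≥ 13 µm
comfortably; the fitted λ changes by <2% between dt = 1 s and dt = 0.2 s.
The source is a delta at x = 0; degradation is spatially uniform; particles
move with the pre-computed D_eff rather than per-step Bernoulli thinning
(equivalent in distribution, faster). Equilibrium particle number is
production/k (e.g. 0.7/1e−4 = 7000); runs of ≥ 6/k equilibrate to within
the Poisson band.

The deterministic oracle is the Neumann eigenfunction solution of
∂C/∂t = D∂²C/∂x² − kC with a boundary source; its steady state is the
cosh profile above. Gradient lengths are estimated by least-squares fits
of exp(−x/λ) (or A·exp(−x/λ) + C with an offset) to max-normalized
profiles.

Time-to-steady-state supports two readouts: total mass, with the closed
form t(f) = −ln(1−f)/k (0.89 h and 1.66 h for 80%/95% at k = 5e−4 s⁻¹),
and the deterministic concentration at a probe point, found by bisection
on the eigenfunction solution. The two differ: near-source probes reach
their plateau earlier than the total mass (≈0.74 h for 80% at x = 10 µm
with the fast-clearance parameters), so reported equilibration times
depend on where the readout is taken; both conventions are exposed rather
than silently picking one.

## Image profiling and clearance fitting

Images are processed as in standard gradient assays: a 36-pixel-tall
region of interest adjacent to the source boundary, binned into 5-pixel
columns (7 × 50.4 µm² windows at 1.4 µm/pixel — the pixel size is an edge
length, which makes the window arithmetic consistent), mean intensity per
window, scalar background subtraction (clipped at zero), normalization to
the bin nearest the source, then an exponential fit with offset. Sets of
embryos can be fitted pooled or individually; both agree on well-behaved
data and both are provided.

Decay series are normalized lane-wise by a loading control and to t = 0,
then fitted with A·exp(−kt) with A free (absorbing t = 0 noise rather than
biasing k); an optional plateau term is available. For rates so slow that
the total decay over the sampled window is a few percent (e.g.
0.003×10⁻⁴ s⁻¹ over 24 h ≈ 2.6%), k is poorly identified and its
confidence interval spans an order of magnitude — the ranking of rates
across constructs is the robust readout, and the recovery tests quantify
exactly this.

## Synthetic data

Generators are pure functions of (parameters, seed) and return the data
together with its ground truth. Noise models are the simplest forms
consistent with each data type: heteroscedastic Gaussian noise
∝ G(τ)·sqrt(τ_min/τ) for correlation curves (larger at short lags, as in
measured curves), multiplicative log-normal noise for FCCS concentration
sets, additive Gaussian noise for images, and multiplicative Gaussian
noise on both band and control intensities for decay series. What passing
the round-trip tests shows is that the estimators recover known parameters
under these noise models at realistic magnitudes; real measurements add
effects deliberately out of scope (detector afterpulsing and cross-talk,
spatially structured autofluorescence, cell movement and division,
non-exponential clearance), so recovery here bounds estimator bias, not
total experimental error.

## Problem sizes

Default test and analysis runs use 1000 particles × 1000 steps for the
slab, 5–60 × 10³ s of 1 s steps for the 1D runs, 200-point correlation
curves, ≤100 seeds for recovery studies, and ≤30 s of photon-oracle trace;
these sizes give sampling errors comfortably inside the stated tolerances
while keeping the full suite under a minute of compute.

## Known limitations

- Ideal FCCS amplitudes (no cross-talk, background or focal-volume
  mismatch corrections).
- The obstacle field is a regular lattice of identical cylinders; real
  cell fields are polydisperse, moving and dividing.
- Binding is quasi-equilibrium with immobile sites only; complexes with
  mobile inhibitors are not transported.
- The 1D source is a delta function; finite source regions would soften
  the near-source profile.
- Scalar per-image background; no spatial background maps.
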