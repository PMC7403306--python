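# Methods

## Governing model and assumptions

The forward model is a Rayleigh–Plesset equation for a spherical bubble
in an incompressible, homogeneous medium, extended with a finite-strain
Neo-Hookean elastic stress and a failure law. Assumptions inherited
from that formulation:

* spherical symmetry; no neighbouring boundaries or bubbles;
* thermal and mass transfer across the bubble wall neglected (inertia
  dominates on the µs scale);
* the gas content is adiabatic with polytropic exponent κ, anchored so
  the internal pressure equals the vapor pressure `p_v` at the maximum
  radius `R_max`; this fixes the equilibrium radius
  `R_0 = R_max (p_v/p_∞)^{1/(3κ)}`;
* a single elastic modulus η (Neo-Hookean); no strain hardening, rate
  dependence, or Mooney–Rivlin/Ogden generality;
* rupture is a sharp transition at a critical **radial** wall strain
  `ε_f,rr` (the fitted quantity; the circumferential failure strain is
  always derived from it, never independent). Both wall-strain
  components are monotone in `R_B/R_0`, so triggering on either gives
  the same failure radius; we standardize on the radial one. After
  rupture the stress plateaus at `E_f = E_L(R_f)` for the rest of the
  growth, and collapse follows the rescaled recovery law continuous
  with the plateau at `R_max`. Because the radial wall strain is
  bounded above by ½, `ε_f,rr ≥ 0.5` cannot be reached and is treated
  as an explicit "never fails" state (`Material.radial_failure_strain
  = None`, infinite failure radius), not an error.

## Defaults and units

Everything internal is SI; µm/µs/kPa appear only in files, configs and
reports. Defaults, all configurable:

| quantity | default | note |
|---|---|---|
| p_∞ | 101 325 Pa | standard atmosphere |
| p_v | 3 169 Pa | water at 25 °C |
| κ | 4/3 | reproduces the published equilibrium-radius triplet (29, 46, 63 µm for R_max = 70, 110, 150 µm) at printed precision |
| ρ | 997 kg/m³ | water at 25 °C |
| ν | 1.0e-6 m²/s | water; hydrogels are >90 % water and their effective ν is not separately measurable here |
| S | 0.072 N/m | water |
| T | 298.15 K | mesh-size estimate only |

ν, S and ρ are held fixed during fitting; only (R_max, η, ε_f,rr[, t₀])
are free.

## Cycle integration

The model pins down exactly one state — the apex `(R_max, Ṙ = 0)` —
since `R_max` both parameterizes the gas law and is a fitted quantity.
The growth half is therefore integrated backward in time from the apex
(plateau law down to `R_f`, intact law below) and the collapse half
forward from the apex (recovery law), each until the velocity turning
point where the gas term, plus Neo-Hookean compression below `R_0`,
arrests the wall. The two halves are joined with `t = 0` at the
growth-side turning point; the cycle time `T_hg` is the time between
turning points. This avoids shooting for the peak against viscous
losses and makes the sampled maximum exactly `R_max` (verified to
0.1 %).

Numerics: LSODA via `scipy.integrate.solve_ivp`, default `rtol = 1e-9`
(`1e-8` inside fitting loops), absolute tolerances 1e-12 m / 1e-6 m/s,
step capped at 1/50 of the water-limit cycle time so events cannot be
stepped over. Phase switches use terminal events on `R_B` crossing
`R_f` and on `Ṙ = 0`, so the stress is continuous at switch points to
solver tolerance; the integration leaves the apex by a second-order
Taylor nudge (~1e-11 s) because the turning-point event function is
identically zero there. An independent fixed-step RK4 integration
reproduces cycle times to 0.1 % (test suite).

### Cycle-endpoint convention

The turning-point definition is a deliberate, documented choice; the
experimental cycle time (first to last photographic frame showing a
bubble) has no unique model counterpart. The convention matters at the
1–3 % level: near each turning point the simulated bubble dwells
~0.5–1 µs at its arrested minimum radius (~10 µm), a regime the
analytic water reference `T_w = 2 · 0.915 · R_max √(ρ/(p_∞ − p_v))`
(which collapses to zero radius) does not contain and a real
plasma-launched bubble does not exhibit. Consequently the simulated
pure-water ratio `T_hg/T_w` is 1.01–1.02 rather than 1, and the
fibrin-parameter ratio computed here is 0.958 where a
visibility-thresholded reading (counting only `R ≳ 25–30 µm`) would
give 0.93–0.94. We report the turning-point value rather than
introduce a threshold parameter tuned to the optics.

## Inverse fit

Bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region-reflective — a box-bounded variant of the
Levenberg–Marquardt scheme) on per-point residuals `model − observed`
in µm; options for per-delay-mean weighting. Model radii at observed
delays come from the simulated cycle; delays outside the cycle window
contribute the distance to the nearest endpoint radius, which
penalizes trial cycles shorter than the data span. Forward-difference
Jacobian with relative step 1e-4 (each residual evaluation is an ODE
solve; cost dominates). Defaults `xtol = 1e-8`, `ftol = 1e-10`.
Bounds: `R_max` within [0.9, 1.5]× the largest observed radius, η in
[0, 200] kPa, `ε_f,rr` in [0, 0.499], `|t₀| ≤ 2 µs`. Initial guess:
largest observed radius; η from a one-point inversion of the observed
cycle shortening; `ε_f,rr = 0.25`. A simulation failure during a trial
step returns large penalty residuals with a warning instead of
raising. Covariance is the standard Gauss–Newton approximation
`σ²(JᵀJ)⁻¹`.

The nuisance offset `t₀` (laser pulse to model inception) exists
because real acquisitions cannot observe the inception instant. It is
fitted by default for instrument data; the synthetic recovery studies
freeze it at zero, because the synthetic acquisition clock *is* the
simulation clock and fitting an offset there only injects variance.

Fits are performed one per sample and then aggregated (mean, n−1
standard deviation; a single fit reports sd 0 by convention) — samples
are never pooled into one fit.

### Identifiability

η and `ε_f,rr` are strongly anti-correlated: the collapse half feels
them only through the plateau stress `E_f(η, ε_f,rr)`, and the growth
half separates them only weakly. Noise therefore moves the two
parameters along a ridge of nearly constant `E_f`. Under the default
synthetic protocol (1 µs steps, 5 replicates, 3 % radius noise) `R_max`
recovers to <1 %, `E_f` to ~±15 %, the Monte-Carlo mean of η to a few
per cent, but single-acquisition η estimates scatter by ~±25 % — the
same order as the across-sample standard deviations reported for real
hydrogels. Fitting without the failure branch on data generated with
failure biases η low in every tested condition (by factors ~2–6),
because a ruptured material mimics a softer intact one.

## Synthetic data

The generator emulates time-resolved single-exposure photography: one
bubble event per laser shot, delays stepped in 1 µs increments over
0–30 µs, ≥5 replicates per delay, and per-replicate multiplicative
Gaussian radius noise (default σ = 3 %, chosen so synthetic fit scatter
is of the order of the published across-sample spreads; the true
instrument noise is unknown and σ is a free knob stated in every output
header). Delays where no bubble exists are omitted, as in the
experiment. What it does **not** emulate: shot-to-shot pulse-energy
jitter, plasma stochasticity, asphericity, optical
point-spread-function structure beyond Gaussian blur, or evolving
material damage across shots — so passing recovery tests demonstrate
correctness of the inference machinery under the stated noise model,
not robustness to every instrument artifact.

## Imaging

2-class k-means on pixel intensity with deterministic min/max center
initialization (reproducible without a seed), darker class = bubble
(configurable polarity), largest connected component, holes filled,
equivalent radius `scale·√(area/π)`. Frames with class centers closer
than 10 % of the intensity range return a flagged no-bubble result
rather than raising; frames touching the image border are flagged and
excluded from series building by default (radius underestimation).
Segmentation is invariant to affine intensity rescaling. The rendered
round trip is accurate to 1 px for radii 10–200 px, blur ≤ 3 px, noise
σ ≤ 10 %.

## Strain fields

Off the wall, strains use the same incompressible spherically-symmetric
kinematics as the governing equation — the only extension consistent
with it: `r(r_ref) = (r_ref³ + R_B³ − R_0³)^{1/3}`, evaluated by
default at `R_B = R_max` (full expansion; `R_B` is a parameter). The
"radial extent of significant strain" depends on an arbitrary
threshold, which is exposed as a parameter (`StrainField.extent_above`)
rather than hard-coded. The characteristic strain rate is the peak
wall circumferential strain divided by the growth time (~2×10⁵ s⁻¹ for
fibrin-like parameters); an instantaneous `dε_θθ/dt` series is also
available.

## Known limitations

* Single cycle only: no rebounds, acoustic emission, or bubble–boundary
  interaction.
* The absolute cycle-time ratio carries the endpoint-convention
  uncertainty described above (~±0.02).
* η/ε_f,rr separation is noise-limited; report `E_f` or aggregate over
  replicated acquisitions when single-shot precision matters.
* The Newtonian reference simulation includes viscosity and surface
  tension by default (both configurable); the analytic water reference
  includes neither.
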