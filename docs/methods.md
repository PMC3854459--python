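# Methods

## Models

### Sequential pool model (SPM)

State vector `[NRP, RRP, RRPCa, RRPCa₂, RRPCa₃, F]`, all in fF
(capacitance is the standard proxy for vesicle membrane area; no
conversion to vesicle counts is attempted). Kinetics:

* **Recruitment.** The Depot pool is treated as infinite, so supply into
  the NRP is a flux (not a first-order rate):
  `k₁(Ca) = k1max·Ca/(K_M+Ca)` fF/s, with back-flow `k₋₁·NRP`.
* **Priming.** NRP ⇌ RRP with the catalyst rate law
  `k₂ = k₂₀ + k₂cat·g`, `k₋₂ = k₋₂₀ + k₋₂cat·g`,
  `g = (Ca/(K_D+Ca))ⁿ` for n independent, identical catalyst sites in
  instantaneous equilibrium with Ca²⁺. `k₋₂cat` is never a free
  parameter: it is always derived as `k₂cat·k₋₂₀/k₂₀`, so the
  equilibrium-invariance property holds by construction, to machine
  precision.
* **Fusion sensor.** The standard three-identical-site scheme: forward
  rates `3k₃Ca, 2k₃Ca, k₃Ca`, backward `k₋₃, 2k₋₃, 3k₋₃` (statistical
  factors only, no extra cooperativity factor), and a fast
  Ca²⁺-independent final step `k₄` from the triply bound state. This
  convention is pinned by the resting fluxes it reproduces (below).

Default parameters (wild-type chromaffin cell): k1max 55 fF/s, K_M
2.3 µM, k₋₁ 0.05 s⁻¹, k₂₀ 0.021 s⁻¹, k₂cat 20 s⁻¹, k₋₂₀ 0.017 s⁻¹,
K_D 100 µM, n 1, k₃ 4.4 s⁻¹µM⁻¹, k₋₃ 56 s⁻¹, k₄ 1450 s⁻¹. With these,
k₂(0.5 µM) = 0.12 s⁻¹, k₋₂(0.5 µM) = 0.10 s⁻¹ (ratio 1.2), and the
analytic steady state at 0.5 µM releases 1.66 fF/s.

**Steady states** are solved exactly: with Ca²⁺ fixed, the five
pre-fusion pools satisfy a linear balance system (F is absorbing); we
solve it with a dense LU factorisation. At Ca = 0 recruitment vanishes
and the system drains, so the steady state is identically zero.

**Synaptotagmin-1-null variants.**

* *Unclamped*: the final fusion barrier is absent — every RRP sensor
  state fuses at the maximal rate k₄ irrespective of Ca²⁺ (the
  Ca²⁺-binding steps are retained but kinetically irrelevant, since the
  pool drains at k₄ either way; whether the unbound state alone or all
  sensor states fuse is numerically indistinguishable at rest). Resting
  release rises to 6.94 fF/s and the fast burst disappears.
* *Destabilized*: the RRP free energy is raised uniformly by
  multiplying **both** components of the backward priming rate (k₋₂₀
  and k₋₂cat) by a factor (default 10), which preserves the catalyst
  interpretation and keeps k₂/k₋₂ Ca²⁺-invariant.

### Parallel pool model (PPM)

State vector `[SRP, SRPCa…₃, RRP, RRPCa…₃, Fs, Fr]`. Depot→SRP
recruitment and the fast (RRP) sensor are identical to the SPM; the SRP
carries its own slower three-site sensor (k₃s 0.5 s⁻¹µM⁻¹, k₋₃s 4 s⁻¹,
k₄s 20 s⁻¹) and fuses in parallel (fluxes accumulate separately in Fs
and Fr). SRP ⇌ RRP interconversion couples the Ca²⁺-free states at
fixed rates k₂ = 0.12, k₋₂ = 0.1 s⁻¹. The **PPM+cat** variant replaces
these fixed rates by the catalyst rate law; since the calibrated
parameter set for that variant is not published, it defaults to the SPM
catalyst values and is fully configurable — PPM+cat results here are
structural, not quantitative.

## Numerical integration

The embedded Runge-Kutta 5(4) pair with Cash-Karp coefficients,
hand-implemented because the integration method is part of the
procedure being reproduced. Step control: error norm
`max|err_i|/(abs_tol + rel_tol·max(|y_i|,|y_i_new|))`, safety factor
0.9, growth `err^(-1/5)` on accepted and `err^(-1/4)` on rejected
steps, clamped to [0.1, 5]. Defaults: rel_tol 1e-8, abs_tol 1e-10 fF,
dense output every 1 ms (capacitance-recording resolution scale).

Protocols are ordered right-continuous segments (`constant`, `step_to`,
`exp_relax`). Integration restarts exactly at every segment boundary —
an adaptive stepper loses its order across a discontinuity of the
driving signal — and steps land exactly on every output-grid point, so
reported samples are solution points, not interpolants. Simulations
start from the analytic steady state at the protocol's initial Ca²⁺
unless an explicit state is given. There is no randomness anywhere in
simulation.

Verification: agreement with a fixed-step classical RK4 oracle
(dt = 1e-5 s) and with scipy's DOP853 to better than 1e-7 relative on
the uncaging protocol; linear mass invariants (total mass minus
integrated Depot exchange) are conserved to solver tolerance, which is
a structural property of Runge-Kutta steps.

## Burst decomposition

Cumulative release is summarised by
`f(t) = A0 + A1(1−e^−(t−t0)/τ1) + A2(1−e^−(t−t0)/τ2) + A3(t−t0)`
over a 5 s window. Conventions:

* `t0` is the **inflection point** of cumulative release after the
  stimulus — the maximum of the discrete first derivative (central
  differences). A tolerance of 1e-9 of the derivative scale
  distinguishes a genuine interior maximum from differencing noise on a
  flat or constant-rate trace; traces without an interior maximum are
  flagged and t0 falls back to the stimulus time. On the standard
  uncaging step the inflection sits ~11 ms after the step (the loading
  time of the sensor cascade), and starting the fit there is what
  recovers the intrinsic RRP depletion rate (~53 s⁻¹, the slowest
  cascade eigenvalue at 25 µM) as the fast rate.
* `A0` is fixed to the trace value at the last sample before t0.
* The five free parameters are fitted by bounded trust-region least
  squares (analytic Jacobian) from a 3×3 multi-start grid
  (τ1 ∈ {5, 20, 100} ms × τ2 ∈ {0.1, 0.3, 1} s, amplitude guesses from
  trace quantiles); bounds τ ∈ [1e-4, 10] s, amplitudes and slope ≥ 0.
  Components are relabelled so τ1 ≤ τ2; fits with τ2/τ1 < 3 are flagged
  as poorly separated, a vanishing A2 as slow-unidentifiable, and a
  residual rms exceeding the burst amplitude as non-identifiable.
* For recovery protocols (double flash) the **second** response is
  fitted with time constants fixed to the first-flash fit and
  amplitudes free (linear least squares with nonnegativity). This
  anchors component identity: a response lacking a genuinely fast phase
  reports a near-zero fast amplitude instead of promoting the slow
  phase to "fast". A fully free fit of the second response is
  ill-posed because the sustained phase decays as Ca²⁺ relaxes and the
  line term is then degenerate with a long exponential.

A note on the slow/fast time-constant ratio: with the default
parameters the intrinsic ratio at 25 µM is ≈13 (53 s⁻¹ vs
k₂(25 µM) = 4.0 s⁻¹), and the full simulate-and-fit pipeline reports
13.5; descriptions of this ratio as "about ten-fold" are a rounding of
the same number.

## Closed-form two-state burst model

For constant rates and no refilling, NRP→RRP→F is linear; the decay
rates are the roots of `λ² − (k₂+k₋₂+k₃)λ + k₂k₃ = 0` (the discriminant
is provably nonnegative for nonnegative rates; λ_slow is computed via
the Vieta product to avoid cancellation). Initial pools are the
priming equilibrium of the total burst load V_tot (default
113.6 fF = 61.3 RRP + 52.3 SRP, the published wild-type pool sizes),
with fusion negligible before the stimulus. Amplitudes follow from
S(0) = V_tot and S′(0) = −k₃·RRP₀ and sum to V_tot exactly; the
measure-zero repeated-root case is evaluated through the
`(V_tot + b·t)e^−λt` limit form. The fusion-rate (`snare_scan`) scan
demonstrates the sequential model's signature coupling — lowering k₃
slows the fast component *and* shifts amplitude toward the slow one —
while the reduced parallel comparator (`ppm_burst_scan`: two pools with
effective first-order fusion rates, interconverting at the fixed PPM
rates) keeps its fast/slow split nearly invariant when the RRP fusion
rate varies. Effective single-pool fusion rates are the slowest decay
eigenvalue of the corresponding sensor cascade at the step Ca²⁺.

## Experiments

* **Flash experiment**: steady state at pre-flash Ca²⁺ (default
  0.5 µM), step at t = 0.5 s (default to 25 µM), integrate a 5 s fit
  window plus 0.1 s margin, decompose.
* **Post-flash scan**: the slow-component rate tracks k₂(Ca) — it
  approaches the catalyzed ceiling k₂cat ≈ 20 s⁻¹ at very high Ca²⁺ and
  half of it at the catalyst K_D (100 µM); the fast rate grows
  monotonically with sensor occupancy.
* **Pre-flash scan**: burst amplitudes are bell-shaped in resting Ca²⁺
  (recruitment-limited at low, depletion-limited at high resting Ca²⁺)
  with a nearly constant fast fraction — the catalyst signature.
* **Selective depletion**: the depletion-pulse length is chosen by
  bisection (2 ms resolution) as the earliest step duration after which
  an immediate probe retains < 15% of the control fast amplitude while
  keeping > 70% of the slow one; the qualitative criterion comes from
  the experimental paradigm, the numbers are this package's
  operationalisation. Probes after an interval at resting Ca²⁺ then
  show the fast component recovering at the expense of the slow one.
  Full recovery is slow: the system's slowest eigenmode at rest has a
  ~50 s time constant, so scans use intervals up to ~60 s.
* **Double flash**: each flash steps Ca²⁺ to 25 µM followed by
  exponential relaxation toward the 0.5 µM baseline (the waveform never
  undershoots the baseline). The measured inter-flash Ca²⁺ time course
  is not tabulated; the default time constant of **2 s** was chosen
  because it reproduces the experimentally reported fast-component
  recovery of the sequential model (~16% fitted vs 18 ± 4% measured at
  an 8 s interval; ~42% vs 35 ± 5% at 22 s) with no change to any model
  parameter. A 5 s relaxation leaves Ca²⁺ near 5 µM at 8 s, where
  ongoing fusion keeps the RRP empty in *both* models and the
  models' distinguishing behaviour is masked — the inter-flash Ca²⁺,
  not the priming kinetics, then rate-limits recovery. Recovery
  fractions are ratios of fitted fast (or slow) amplitudes,
  flash 2 / flash 1. At an 8 s interval the SPM recovers ~16% of the
  fast component, the PPM exactly none (its SRP→RRP step ignores the
  elevated Ca²⁺), and PPM+cat is intermediate.

## Synthetic fixtures

`generate_fixture` adds seeded Gaussian noise to the **capacitance
observable only** (pools stay clean), emulating measurement noise of a
capacitance recording at 1 ms sampling; 0.5 fF noise on a ~100 fF burst
is a realistic signal-to-noise for chromaffin-cell recordings. It does
not emulate Ca²⁺-measurement error, drift, endocytosis, or cell-to-cell
parameter variability — parameter-recovery results on fixtures
therefore validate the fitting machinery, not biological inference
under model misspecification.

## Problem sizes and runtime

Simulations integrate 5–70 s of model time at 1 ms dense output
(~5 000–70 000 solution points); scans use 5–8 conditions; the
parameter-recovery statistic uses 100 noise seeds on a 5 001-point
synthetic trace. The full test suite runs in about two minutes on one
CPU.

## Known limitations

* Spatially homogeneous Ca²⁺ only — no microdomain coupling, so
  synaptic geometries are out of scope.
* The Depot is infinite and the catalyst unlimited; neither saturates.
* PPM+cat uses the SPM catalyst parameters by default (the calibrated
  set is not published); its curves are qualitative.
* The double-flash inter-stimulus Ca²⁺ waveform is a single-exponential
  approximation with a configurable time constant.
* The burst decomposition reports no parameter uncertainties beyond the
  residual rms; fits at very low post-flash Ca²⁺ are flagged rather
  than resolved (fast and slow phases are not kinetically separable
  there).
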