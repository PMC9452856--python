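# Methods

## Model

Two populations of Kuramoto phase oscillators — the retinorecipient ventral
core (υ) and the dorsal shell (d) of the SCN — interact all-to-all within and
between groups.  The model assumes SCN clock cells are self-sustained, nearly
sinusoidal oscillators, so each cell is a phase θ_i with a natural frequency
ω_i; dense connectivity (hundreds of synapses per neuron) justifies the
mean-field (all-to-all) coupling.  Natural frequencies follow a
Cauchy–Lorentz law with location ω̄ and half width at half maximum Δ per
group; this specific heavy-tailed choice is what makes the macroscopic
reduction exact: the group order parameter z = ρe^{iψ} then obeys the closed
four-dimensional system given in the README, and the microscopic simulator
exists in this package precisely to validate that reduction numerically
rather than assume it.

A periodic light cue of strength F and period T acts on the core only and is
kept explicitly in the equations (rotating-frame form), so nonlinear effects
of the cue are captured.  Constant darkness (DD) is F = 0.  Constant light
(LL) is modelled phenomenologically: the periodic cue term is replaced by a
signed constant B that shifts every core oscillator's frequency,
ω̄_υ → ω̄_υ + B.  |B| plays the role of light intensity; B < 0 describes
nocturnal animals and B > 0 diurnal ones — the sign convention that
reproduces Aschoff's first rule.

## Parameters, units, defaults

| parameter | meaning | unit | default (mouse) |
|---|---|---|---|
| τ_υ, τ_d | mean free-running period, core / shell | h | 25.1 / 23.3 |
| σ_υ, σ_d | SD of free-running periods | h | 1.3 / 1.9 |
| K_υυ, K_dd | intracoupling, core / shell | core-spread units | 5.6 / 4.0 |
| K_υd, K_dυ | intercoupling core→shell / shell→core | core-spread units | 1.1 / 0.5 |
| F | light-cue strength (LD) | core-spread units | 1.5 |

Derived: ω̄ = 2π/τ and Δ = 2πσ/τ² (the small-spread propagation of a period
SD into a frequency SD, identified with the Lorentzian HWHM).  All dynamical
computation is dimensionless — frequencies divided by the dimensional core
spread Δ_υ ≈ 0.01297 rad/h, time multiplied by it — so one dimensionless time
unit is ≈77.13 h and the dimensionless core spread is exactly 1.  A second
formula for Δ_υ with π in place of 2π circulates in summaries of this
calibration; only the 2π form reproduces the standard dimensionless values
(ω̄_υ = 19.3, ω̄_d = 20.8, Δ_d = 1.7), so the package treats the π variant as
a typo and uses 2π throughout.  We derive the dimensionless values exactly
from the hour-valued inputs rather than using those rounded figures.

The intracoupling defaults come from the stationary single-group relation
K = 2Δ/(1−ρ²) evaluated at target synchronization indices ρ_υ = 0.8 and
ρ_d = 0.4 — the 2:1 ratio is a modelling convention, kept only as the
documented origin of the defaults — which places the shell ~18% above its
critical coupling 2Δ_d = 3.4 (near-critical) and the core ~180% above its
critical 2Δ_υ = 2.0.  The intercouplings and F were calibrated so the
entrained shell leads the core by 2.3 h at T = 24 h.  A second preset
(`table1-reference`) keeps the literature shell period τ_d = 23.9 h; with it
the dimensionless frequency difference ω̄_d − ω̄_υ evaluates to 0.97, the
number usually quoted for the minimum total intercoupling that still permits
core–shell synchronization.  (The analogous single-group bound
K_υd > ω̄_d − ω_F "= 0.15" sometimes quoted for T = 24 h is not reproducible
under any unit convention we tried — the model column gives 0.61, the
reference column 0.085 — so the package implements the inequality
symbolically and does not hard-code that number.)

## Numerical choices

- **Integration.**  DOP853 with rtol 1e-9 / atol 1e-10 and dense output,
  resampled onto a uniform grid (default 0.25 h).  Bifurcation localization
  to 0.005 h needs this tight local error.  ρ is clipped to [0, 1] only
  within floating tolerance; clip events are counted and reported.
- **ρ → 0 regularization.**  The phase equations divide by ρ; the denominator
  is floored at 1e-9.  The phase of an incoherent group is physically
  meaningless, and no studied protocol integrates through the incoherent
  state; the floor only prevents overflow.
- **Initial condition.**  (ρ_υ, ψ_υ, ρ_d, ψ_d) = (0.5, 0, 0.5, 0) for every
  protocol, overridable; every result artifact records the initial state that
  produced it because multistability is possible near bifurcations.
- **Transients and records.**  50 drive periods discarded, 200 recorded (DD
  and LL use a nominal 24-h period for sizing).  0.01 h period resolution at
  24 h requires long records plus peak interpolation.
- **Spectra.**  Hann-tapered periodogram normalized so total power
  approximates the series variance; component period refined by quadratic
  interpolation of log-power through the three bins around each local
  maximum; component intensity is lobe-integrated power (between adjacent
  local minima), so a cosine of amplitude A has intensity A²/2.  Absolute
  intensities are normalization-dependent; only ratios and presence/absence
  are treated as meaningful.  A component is drive-locked when its period is
  within 0.05 h of T; a second rhythm must exceed 1% of the dominant
  component's intensity.
- **Drift-rate cross-check.**  The dissociated frequency is independently
  estimated from a least-squares line through the unwrapped group phase; the
  two estimators agree to <0.01 h wherever both are defined.
- **Fixed points.**  Powell-hybrid root search with the analytic Jacobian
  (cross-checked against central differences in the tests); convergence is
  judged by the residual (max |dy/dt| < 1e-10), and a settle-by-integration
  fallback handles cold starts that miss the attractor.  Stability labels
  come from a documented eigenvalue decision table; under DD/LL the relevant
  object is the three-dimensional relative system (ρ_υ, ρ_d, ψ_d−ψ_υ), whose
  fixed point is the rigidly rotating synchronized state and whose Hopf
  instability is the onset of dissociation.

## Locating the entrainment limits

Two locators are computed and must agree within 0.06 h:

1. **Spectral (reported).**  Bisection on "does the shell observable carry a
   non-drive-locked component above the 1% floor?", each trial starting from
   the default initial state so that every trial sees the same approach to
   the attractor.  A state-continuation variant (reusing the previous
   endpoint's final state) is available and used for the hysteresis
   down-sweep near the lower limit; sweep direction matters near a
   saddle-node, so both are exposed.
2. **Stability (cross-check + labels).**  Bisection on the leading eigenvalue
   of the entrained fixed point, with continuation of the root between
   trials.  The eigenvalue structure at the crossing labels the bifurcation:
   a complex pair (Hopf) at the upper limit, a real zero crossing
   (saddle-node) at the lower limit.

The 0.06 h agreement band, rather than twice the 0.005 h bisection tolerance,
is deliberate: near a supercritical Hopf the decay/growth rate vanishes
linearly in T, so within a boundary layer of a few hundredths of an hour no
finite record can distinguish a slowly decaying ring-down from a sustained
second rhythm.  The spectral onset therefore sits systematically inside the
linear-stability boundary by about the layer width (here ≈0.05 h); both
numbers are reported.  At the saddle-node side there is no ring-down and the
two locators agree to ~0.015 h.

- **Near-limit dissociation gaps** (|T_sr − limit| just outside each limit)
  are measured 0.02 h outside the *bifurcation* points and referenced to
  them, because the gaps characterize the bifurcation itself: at the
  saddle-node the dissociated period approaches the drive period continuously
  (phase slips of diverging period), while at the Hopf the dissociated line
  appears at the drive frequency plus the Hopf frequency, a finite jump of
  ≈1.7 h.  Below the lower limit the dissociated line sits only ~0.2 h from
  the drive line, so those records are lengthened to 800 drive periods; at
  200 periods the peak picker cannot separate the two lines and lands on an
  unresolved sideband.
- **Critical light intensity.**  Onset of LL dissociation is located by
  bisection on the leading eigenvalue of the relative system (a Hopf
  instability), then confirmed spectrally 0.05 on either side: second rhythm
  present outside, absent inside.  Bisection on spectral presence alone is
  ill-posed here for the ring-down reason above, compounded by the very small
  amplitude of the core's dissociated component near onset.

## The microscopic oracle

`simulate_microscopic` integrates the N-oscillator system directly (the
coupling sums collapse onto the group order parameters, so a step costs
O(N)), with fixed-step RK4 in dimensionless time (default step 0.002, chosen
so halving it moves the final ρ by <1e-4; adaptive control over ~4·10⁴
near-identical phase equations buys nothing).  Frequencies are i.i.d.
Cauchy draws; draws beyond 50 HWHM of the location are redrawn and counted —
such oscillators never lock, contribute only O(1/N) drift to z, and make the
system needlessly stiff; the threshold is configurable and its effect is
covered by the N-scaling check.  Initial phases are wrapped-normal with
circular spread chosen to hit a requested initial coherence
(ρ = exp(−s²/2) inverted).  N is an artifact choice for validation — the
macroscopic results do not depend on it — and the tests check agreement with
the reduced model at the entrained operating point within 3/√N in ρ and 5/√N
rad in phase, plus the 1/√N scaling of the fluctuating discrepancy.

What the oracle does and does not emulate: it validates the mean-field
reduction for Cauchy-distributed, sinusoidally coupled phase oscillators —
the model's own microscopic premise.  It does not add biological realism
(relaxation-oscillator waveforms, sparse or distance-dependent topology,
synaptic noise, neuropeptide kinetics), so passing tests demonstrate internal
consistency of the reduction, not fidelity of the Kuramoto abstraction to SCN
electrophysiology.

## Closed-form relations

All stationary identities (entrained phase difference, free-running frequency
as the weighted mean (aω̄_υ + bω̄_d)/(a+b) with weights a = ρ_υ²K_υd(1+ρ_d²),
b = ρ_d²K_dυ(1+ρ_υ²), the DD phase difference, the total-intercoupling
synchronization bound, and their LL variants with ω̄_υ + B) are implemented
as pure functions and verified against simulated stationary states to 1e-6.
Arcsines are taken on the principal branch [−π/2, π/2]; the entrained phase
difference lies there, but free-running stationary phase differences can
exceed π/2 (the identities then still close in sine form, and the tests check
them that way).  Negative-intercoupling cases use the same rational
expressions with sign-aware reporting — the published rearrangements are
algebraically identical — and the report flags when the free-running period
escapes the interval (τ_d, τ_υ).

## Known limitations

- The LL light model is phenomenological (a frequency offset); intensity in
  lux maps to B only up to an unknown monotone calibration.
- Only symmetric LD cycles and two groups are implemented; asymmetric
  photoperiods, antiphase splitting, jet-lag protocols, and multi-hemisphere
  configurations are out of scope.
- Entrainment limits carry the ring-down ambiguity described above; any
  single number for the upper limit is procedure-dependent at the few-hundredths-of-an-hour
  level, which is why both locators are always reported.
- The nocturnal critical intensity is a supercritical Hopf at |B| ≈ 0.285
  under this calibration (ascending and descending sweeps agree; no
  bistability was found), with a free-running period of ≈25.28 h at onset and
  25.21 h at |B| = 0.24.
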