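# coreshell

A reduced two-population Kuramoto model of the suprachiasmatic nucleus (SCN),
the brain's master circadian pacemaker, for anyone studying how the SCN's
core–shell organization shapes entrainment to light, anticipation of daily
events, and the breakdown of synchronization (rhythm dissociation) under
abnormal lighting.

The SCN is modelled as two all-to-all coupled groups of phase oscillators: the
retinorecipient ventral **core** (υ) and the dorsal **shell** (d).  Each group
m is summarised by the complex order parameter

    z_m = ρ_m e^{iψ_m} = (1/N_m) Σ_j e^{iθ_j},

whose modulus ρ_m (synchronization index) and argument ψ_m (group phase)
follow closed macroscopic equations when the natural frequencies are
Cauchy–Lorentz distributed (location ω̄, half width at half maximum Δ).  In
the frame rotating at the light–dark (LD) drive frequency ω_F = 2π/T:

    dρ_υ/dt = −ρ_υ Δ_υ + ½K_υυ ρ_υ(1−ρ_υ²) + ½F(1−ρ_υ²)cos ψ_υ
              + ½K_dυ ρ_d (1−ρ_υ²) cos(ψ_d−ψ_υ)
    dψ_υ/dt = −Ω_υ − ½F (1+ρ_υ²)/ρ_υ sin ψ_υ
              + ½K_dυ ρ_d (1+ρ_υ²)/ρ_υ sin(ψ_d−ψ_υ)
    dρ_d/dt = −ρ_d Δ_d + ½K_dd ρ_d(1−ρ_d²) + ½K_υd ρ_υ (1−ρ_d²) cos(ψ_υ−ψ_d)
    dψ_d/dt = −Ω_d + ½K_υd ρ_υ (1+ρ_d²)/ρ_d sin(ψ_υ−ψ_d)

with detunings Ω = ω_F − ω̄ and the light cue of strength F acting on the
core only.  Nine biologically meaningful parameters define the model — the
mean free-running periods τ_υ, τ_d and period spreads σ_υ, σ_d (hours), the
intracouplings K_υυ, K_dd, the intercouplings K_υd, K_dυ, and F — and a mouse
calibration is packaged as the `table1` preset.  Constant darkness (DD) sets
F = 0; constant light (LL) replaces the periodic cue with a signed intensity
B that shifts the core's mean frequency (ω̄_υ → ω̄_υ + B).

The package provides:

- `reduced_model` — integration, fixed points, analytic Jacobian, and
  Hopf/saddle-node bifurcation location for the macroscopic equations;
- `microscopic` — a direct N-oscillator simulator (the correctness oracle for
  the reduction, with O(1/√N) agreement checked in the tests);
- `spectral` — decomposition of the lab-frame activity proxy Re(z) into
  independent rhythm components, for detecting dissociated rhythms;
- `analytic` — the closed-form stationary relations (entrained phase
  difference, free-running frequency as a coupling-weighted mean, the
  synchronization bound on the total intercoupling, LL renormalization);
- `protocols` — the experiments: entrainment range, anticipation, the
  dissociation curve, DD/LL runs, critical light intensity, Aschoff scans;
- a `coreshell` CLI exposing each protocol with CSV + JSON-sidecar output.

## Worked example

```python
import coreshell as cs

params = cs.table1()                       # packaged mouse calibration
report, dpsi, lead = cs.entrained_state(params, 24.0)
print(f"core-shell phase difference: {dpsi:.3f} rad")
print(f"shell peak leads core by:    {lead:.2f} h")

dd = cs.dd_protocol(params)
print(f"free-running period (DD):    {dd.tau_dd_h:.2f} h")

rng = cs.entrainment_range(params)
print(f"entrainment range:           {rng.lle_h:.2f} - {rng.ule_h:.2f} h")
print(f"bifurcations:                {rng.lower_label} / {rng.upper_label}")
```

prints

```
core-shell phase difference: 0.605 rad
shell peak leads core by:    2.31 h
free-running period (DD):    24.84 h
entrainment range:           23.25 - 25.28 h
bifurcations:                saddle_node_marginal / hopf_marginal
```

Read: entrained to a 24-h LD cycle, the shell's collective phase runs 0.605
rad (≈35°) ahead of the core, so shell activity peaks 2.3 h before the
light-locked core peak — the anatomical basis for anticipating regular
events.  Without any light cue the coupled system free-runs at 24.84 h, a
compromise between the core's 25.1 h and the shell's 23.3 h weighted by the
intercouplings.  Entrainment only holds for LD periods between about 23.25
and 25.28 h; pushing T below the lower limit destroys the entrained state in
a saddle-node bifurcation, pushing it above the upper limit in a supercritical
Hopf bifurcation, and in both cases a second (dissociated) rhythm appears in
the activity spectrum.

The same protocols are available from the shell, e.g.

```
coreshell range --preset table1 --out range.csv
coreshell dd    --preset table1 --out dd.csv
coreshell bc    --preset table1 --sign nocturnal --out bc.csv
```

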