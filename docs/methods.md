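# Methods

## Model overview

`chemonav` couples two layers:

1. **Receptor-modulation kinetics** (module `kinetics`): a linear
   mass-action system for one ligand–receptor pair at one
   receptor-expressing unit, with four pools (free surface receptors,
   active complexes, desensitized surface complexes, internalized
   receptors) and five rate constants. Binding activates the receptor;
   active complexes desensitize (homologously — only the receptor's own
   ligand silences it); desensitized complexes internalize; internalized
   receptors are re-expressed to the surface. Ligand dissociation from
   desensitized surface complexes is neglected, and ligand is not depleted
   by binding.
2. **Gradient sensing and migration** (modules `orientation`,
   `migration`): the cell is a ring of receptor-expressing units (four by
   default, on the ±x/±y axes at r = 5 µm). The orientation vector is the
   front–back difference in active complexes, summed over ligands; its
   magnitude against a fixed threshold selects directed migration versus
   chemokinesis in a biased persistent random walk.

Both layers are deterministic given a seed; the only stochastic elements
are the initial heading and the sub-threshold random re-orientations.

### Kinetic scheme closure

The literature parameter set distinguishes an internalized complex from an
intracellular free receptor but supplies no rate connecting them. With
exactly five rate constants available, the package merges the two into a
single internalized pool `R_int`, fed at `k_i` and recycled at `k_up` —
one transition per constant. The steady state then has the closed form

    LR* = R_u·k_f·L / [(k_r + k_des) + k_f·L·(1 + k_des/k_i + k_des/k_up)]

with `LR_d = (k_des/k_i)·LR*` and `R_int = (k_des/k_up)·LR*`; at
`k_des = 0` it reduces exactly to the Langmuir isotherm
`R_u·L/(K_d + L)`, `K_d = k_r/k_f = 4.405 nM`.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| k_f | association rate | 0.084 (= 8.4×10⁷ M⁻¹s⁻¹) | nM⁻¹ s⁻¹ |
| k_r | dissociation rate (low-affinity) | 0.37 | s⁻¹ |
| k_des | homologous desensitization rate | 0.065 (0 = nondesensitizable) | s⁻¹ |
| k_i | internalization rate | 0.0033 | s⁻¹ |
| k_up | re-expression (up-regulation) rate | 0.004 | s⁻¹ |
| R_tot | receptors per cell | 25 000 | counts |
| R_u | receptor endowment per unit | 12 500 = R_tot/2 | counts |
| L_max, L_0, A, n | field peak, basal, radius, power | 17.6, 0, 1000, 3 | nM, nM, µm, – |
| r, N | unit ring radius, unit count | 5, 4 | µm, – |
| speed | migration speed | 10 | µm/min |
| threshold | directed-migration gate on \|ΔLR*\| | 10 (inclusive: ≥) | counts |
| tau_opt / tau_min | longest / shortest step time | 2.5 / 0.25 | min |
| v_sat | \|ΔLR*\| at which the step time saturates | 100 | counts |
| substep_dt | turning/advection sub-step | 0.05 | min |
| ode_dt | RK4 step | 0.1 | s |

**Per-unit receptor endowment.** The source parameterization fixes only
the whole-cell total R_tot = 25 000. The package assigns
R_u = R_tot/2 per unit: with the canonical 17.6 nM field this calibration
places the desensitizable directed band (|ΔLR*| ≥ 10) in the outer,
low-concentration region (ρ ≈ 765–900 µm) while the inner region is
orientation-blind, which is the qualitative structure of the
desensitizable orientation map; an R_tot/4 split leaves essentially no
directed region. A side effect worth knowing: at L_max = 2 nM the
desensitizable field has *no* supra-threshold band anywhere (max |ΔLR*| ≈
6–7), so low-dose chemotaxis demonstrations use the 20 nM preset.

**Step-time and turning constants.** The model prescribes
proportionality of both persistence time and turning rate to |ΔLR*| with
an optimal step of 2.5 min, but no proportionality constants. The package
uses τ = clamp(tau_opt·|v|/v_sat, tau_min, tau_opt) with v_sat = 100, and
an angular speed ω = (π/tau_opt)·(|v|/v_sat) capped at the target so the
heading never overshoots — normalized so a saturating signal completes a
π turn within one optimal step. All three constants are config fields.

**Sub-threshold (chemokinesis) steps** re-orient instantly to a uniformly
drawn heading and last tau_min. Applying the proportional turning law at
|v| ≈ 0 would freeze the heading and make the zero-field track a straight
line rather than a random walk, so the discrete re-orientation draw is
used instead. This yields an uncorrelated walk with step 2.5 µm
(diffusivity ≈ 6 µm²/min), the model's rendering of random neutrophil
motility.

## Numerics

* RK4 with dt = 0.1 s is comfortably stable for the default rates
  at field concentrations (fastest rate k_f·L ≈ 1.5 s⁻¹ at 17.6 nM; the
  stability limit is dt·rate ≲ 2.8). Sweep tests that push k_f·L toward
  50 s⁻¹ use dt = 0.02 s.
* Within a migration sub-step (3 s; the cell moves 0.5 µm) the ligand
  concentration at each unit is frozen at its sub-step-start value. The
  kinetics are then linear with constant coefficients, and the classical
  RK4 update equals its degree-4 Taylor propagator
  `P = I + A + A²/2 + A³/6 + A⁴/24`, `A = dt·M`; the sub-step is computed
  as `P^30 · state` — algebraically identical to 30 explicit RK4 steps
  (verified in the tests) at a fraction of the cost. Because every column
  of `M` sums to zero, every column of `P` sums to one and receptor
  conservation is preserved to machine precision at every step.
* Negative overshoot below 10⁻⁹·R_u is clamped to zero; anything larger
  raises a step-size error rather than being silently repaired.
* Threshold comparison is inclusive: |ΔLR*| = 10 counts as directed.
* The N-unit orientation sum is normalized by N/4 so it reduces exactly
  to the 4-unit definition, making the 4- vs 36-/72-unit comparison
  well-posed; the comparison metric is the relative difference of vector
  magnitudes at the same position.
* Track bookkeeping samples every sub-step, so consecutive samples are
  straight segments of exactly speed·Δt and the total path length is
  exactly speed·total_time.
* RNG contract: one `numpy` Generator per track; draws occur in fixed
  order (one uniform heading at track start, one uniform angle per random
  step). Cohorts give track *i* the seed base_seed + i.

## Preset geometry conventions

Source coordinates and start positions are conventions of this package,
exposed as overridable config:

* **Single-gradient presets**: one source at the origin; 7 starts on the
  ρ = 900 µm ring; 150 min.
* **Opposing presets**: two different ligands with identical profiles at
  (±700, 0) µm — separation 1400 µm, fields overlapping over
  |x| < 300 µm; 12 starts along the axis; 75 min. The separation is
  deliberately *not* 1000 µm: with L_max = 17.6 nM the nondesensitizable
  orientation strength s(ρ) is stationary exactly at ρ = 500 µm (the
  Langmuir front–back difference peaks where L = K_d/2 = 2.202 nM, and
  L(500) = L_max/8 = 2.2 nM), so a 1000-µm separation puts the balanced
  midpoint on a bifurcation where the escape of nondesensitizable cells
  is marginal. At separation 1400 the midpoint lies on the decreasing
  branch of s(ρ): nondesensitizable cells are captured by the nearer
  source within ~10 µm of the midpoint (escape), while desensitizable
  cells are pushed back toward it from ~±150 µm (trapping).
* **Angled presets**: sources 1150 µm apart at (±575, 995.9) µm with a
  3×3 start cluster at (0, 300) ± 40 µm — about 900 µm from each source,
  an approximately equilateral triangle. The same ρ = 500 µm degeneracy
  motivates the 1150-µm separation: the sources' midpoint then lies
  575 µm from each source, past the orientation-strength maximum, so
  nearer-source capture of nondesensitizable cells in different-ligand
  angled gradients is robust rather than marginal. A start cluster at the
  exact far vertex of a side-1000 equilateral triangle would sit exactly
  at the field boundary (ρ = 1000 = A) and sense nothing.
* **Navigation presets** (150 min): the distant target L3 sits at
  (0, 1340) µm — outside detection range of the starts (ρ ≈ 1040 > A).
  nav_B adds a single nearer source at (0, 1100); nav_C/D add the angled
  pair (identical/different ligands). The distances are chosen so the
  desensitizable arrest band (765–900 µm at 17.6 nM) separates the
  configurations: only the balanced corridor produced by two *different*
  ligands (nav_D) carries cells into L3's detection band.

## What the simulations emulate — and what they do not

The scenario presets emulate the study conditions: fixed truncated
power-law fields (a stand-in for quasi-steady point-source diffusion of
~10 kDa chemokines), equal receptor totals for all ligands, shared
downstream signaling, constant migration speed, and no cell–cell
interaction, volume exclusion, ligand depletion, or receptor synthesis.
Passing tests therefore show that homologous desensitization is
*sufficient* to produce the navigation patterns under these idealized
fields; they say nothing about real tissue gradients (which evolve in
time), heterologous desensitization, or signaling hierarchies between
attractants.

## Problem sizes

The stochastic behavior suite runs ~20 seeds (or 9–24 tracks) per
condition with the preset durations (75/150 min of simulated time); the
whole suite completes in about a minute on one CPU. The kinetics oracle
suite integrates 20 random parameter draws to t = 2 h against the
closed-form steady state.

## Known limitations

* **Identical-ligand angled gradients with nondesensitizable receptors.**
  The expected endpoint pattern — cells accumulating at the midpoint
  concentration peak formed by superposition — is not reproduced, and
  cannot be under this field kernel together with the other angled
  patterns. For two identical superposed power sources the midpoint is a
  *saddle* of the combined concentration: along the inter-source axis it
  is a minimum (u³ + v³ at fixed u+v is minimized at u = v), and the
  nearer source's gradient is always the steeper one, so the bisector
  approach is laterally unstable and nondesensitizable cohorts end at a
  source (the corresponding acceptance assertion fails and is left
  failing). Retaining cells at the saddle would require near-saturating
  overlap (sources ≲ 600 µm apart), which provably places the
  different-ligand balance point before the orientation-strength maximum
  and destroys the nearer-source capture pattern — the two patterns are
  mutually exclusive in a single geometry.
* The 2 nM desensitizable field is everywhere sub-threshold under the
  R_u = R_tot/2 calibration (see above).
* Fields are static; moving or time-evolving sources are out of scope.
* The per-unit receptor split, the step-time/turning constants and the
  sub-threshold persistence are modeling conventions, not measured
  values; all are exposed in config.
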