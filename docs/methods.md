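# Methods

## Model structure and assumptions

The model is a deliberately coarse, phenomenological description of central
carbon metabolism as seen by a kinetic extracellular-acidification assay.
Ten dynamic species occupy three compartments of unit volume; nine
reactions carry first-order mass-action rate laws, with three structural
refinements:

* uptake reactions (1, 9) are scaled by constant dimensionless *capacities*
  standing in for transporter abundance; mitochondrial pyruvate entry (5)
  is scaled by the remaining headroom `(Capacity_M − TCA)`, which
  self-corrects — the flux reverses if the TCA pool ever exceeds the
  capacity — so no clamp is applied to it;
* intracellular glutamine amplifies TCA→ETC flux through `(1 + Gln/10)`,
  the model's expression of glutamine-stimulated oxidative metabolism; the
  `Gln` here is the instantaneous intracellular species, so the
  amplification builds up as glutamine is imported;
* the modulators enter as factors `1 ± dose × sensitivity`:
  `(1 + Oligo·i2 − 2DG·i1)` on glycolysis (oligomycin stimulates it
  indirectly via energy-stress signalling; 2-deoxyglucose competitively
  inhibits it) and `(1 − Oligo·i2)` on TCA→ETC flux.

Every reaction is 1:1 — one unit of substrate becomes one unit of product.
Lumping the ten enzymatic steps of glycolysis into reaction 2 therefore
also ignores the 1-glucose→2-pyruvate stoichiometry; concentrations are
"model units", nominally µM, and the invariant total pool is the sum of the
ten species. The pentose-phosphate, hexosamine and reductive-carboxylation
branches are out of model scope, as is the pH chemistry of the sensor
itself.

**Units.** Time is minutes and rate constants min⁻¹ throughout. The assay
grid (350 samples at 0.34 min) and the 120-min horizon are stated in
minutes, which makes minutes the only self-consistent choice; configuration
files carry an explicit `units` block to make the commitment visible.

**Modulator factors are evaluated literally by default.** At extreme
dose × sensitivity products the bracketed factors go negative and reaction
6 can run backwards; that is what the printed equations do, so the default
preserves it. `clamp_modulator_factors` floors both factors at zero as an
explicit opt-in. SBML export refuses clamped scenarios, since a floored
factor has no representation in a plain kinetic law.

## The calibrated reference constants

No complete optimised constant set is published for this model, so the
package ships one calibrated to the documented behaviours, all of which are
re-checked by `calibrate_reference_parameters()` at run time:

| constant | value | role |
|----------|-------|------|
| kf_Glc | 1.45e-4 | glucose uptake; with Capacity_Glc = 200 gives the 0.029 min⁻¹ timescale that places the lactate plateau onset at 82.96 min |
| kf_Gln | 2.80e-4 | glutamine uptake; kf_Gln·100 < kf_Glc·200 keeps glutamine consumption slower than glucose, as active amino-acid transport is |
| kf_1, kr_1 | 0.1, 0.01 | lumped glycolysis (fast relative to uptake) |
| kf_2, kr_2 | 0.8, 0.05 | fermentation branch at the pyruvate junction |
| kf_3, kr_3 | 0.1, 0.01 | lactate export; kr_3 = 0.01 is the printed slow re-uptake value |
| kf_4, kr_4 | 0.03, 0.005 | mitochondrial pyruvate entry and leak-back |
| kf_5 = kf_6 | 0.5 | TCA→ETC and TCA→CellComponents; equality makes the glucose-only ETC and cell-component curves coincide |
| kf_7 | 0.005 | mitochondrial glutamine entry; small, so imported glutamine accumulates and the (1+Gln/10) amplification is strong |
| i1 | 0.1 | 2DG sensitivity: dose 9.9 gives factor 0.01, an almost complete glycolytic block |
| i2 | 0.1133 | oligomycin sensitivity: dose 8.7 gives (1−0.9857) = 0.0143 on TCA→ETC flux |

The value of `i2` deserves its own paragraph, because the natural first
choice — `i2 = 0.1`, mirroring `i1` — turns out to be structurally
incompatible with three behaviours the set must reproduce *simultaneously*:
(i) glutamine roughly halves final lactate, (ii) final lactate is nearly
flat across Gln_ex = 1000–6000, and (iii) oligomycin at dose 8.7 restores
lactate to the glucose-only level. Flatness across the sweep requires the
glutamine amplification of reaction 6 to be saturating — intracellular Gln
in the hundreds, so the drain on the TCA pool is overwhelming at every
sweep value. But with `i2 = 0.1`, dose 8.7 leaves 13 % of that overwhelming
drain active, which is still overwhelming: lactate stays suppressed and
(iii) fails for any constant set satisfying (i) and (ii). Oligomycin can
only restore lactate if its factor nearly cancels the amplification, i.e.
`(1 − 8.7·i2)·(1 + Gln/10) ≈ 1`. `i2 = 0.1133` achieves that while keeping
the bracketed factor sub-unity at the best-fit dose, which is the point of
sensitivities near 0.1 on a 1–10 dose scale. The class default for both
sensitivities remains 0.1; the calibrated value ships in the reference
file, and both are ordinary configuration values.

With this set the mechanism of each condition is: glucose-only — the TCA
pool saturates its capacity, mitochondrial throughput is drain-limited and
small, most carbon exits as lactate; +glutamine — the amplified drain keeps
the TCA pool nearly empty, pyruvate flows into the headroom and ETC output
overtakes lactate; +oligomycin — the drain is knocked back to roughly its
glucose-only size, the pool refills, lactate recovers; +2DG — glycolysis is
throttled to 1 %, intracellular glucose accumulates, and the slow late
lactate rise is glutamine carbon leaking back through the reversible
mitochondrial entry (kr_4).

## Simulation

`simulate` integrates with LSODA (stiff-capable, adaptive) at rtol 1e-8 /
atol 1e-9 and evaluates the dense output on the sampling grid
t_i = i·0.34 min, i = 0…349 (last sample 118.66 min), mirroring the
plate-reader protocol of 350 cycles over 120 min; fluxes are recomputed
from the solved states at each output time. Total-pool conservation is
monitored to within 10 × rtol × initial pool. An independent fixed-step
classical Runge-Kutta integrator (`simulate_fixed_step`, default step
1e-3 min, no error control, no dense output) serves as an integration
oracle in the tests; the two paths agree to 1e-5 relative on the default
scenario.

**Plateau onset** is operationalised as the earliest sample at which a
signal reaches 97 % of its run maximum (earliest sample wins ties; a
constant-zero signal reports onset 0 and a degenerate flag). The 0.97
threshold is a package choice — "plateau" has no printed definition — set
so that a saturating glucose-only lactate trace yields an onset near the
measured 83 min; it is an explicit argument of `summarize`.

Default sweep ranges reproduce the standard figures: glucose 2000–20000,
glutamine 1000–6000, both modulators 1–10 dose units.

## Synthetic plate data

`generate_plate` emulates the statistical structure of the real experiment:
triplicate wells for each of the four conditions plus triplicate cell-free
controls, all on the shared 350-sample grid. A treated well is
`gain·Lac_ex(t) + offset`, plus a drift term `offset·drift_per_min·t`
shared by all wells, times multiplicative Gaussian noise of coefficient
`noise_cv` drawn from a per-well substream of the seed (so plates are
bit-reproducible and replicates independent). Control wells carry offset,
drift and noise only. Defaults — gain 5, offset 25000 RFU, noise_cv 0.03,
drift 5e-4 min⁻¹ — are invented: the real instrument's absolute RFU scale
is unconstrained, only trace shape matters. Normalisation subtracts the
pointwise control-well mean, exactly cancelling offset and drift (additive
disturbances), which is why subtraction rather than division is used.

What the generator does *not* emulate: instrument optics (lag/integration
windows, detector gain), well-position and evaporation effects, the CO₂
contribution to acidification (subsumed in offset/noise), and any
systematic mismatch between the model family and real cellular kinetics.
Passing recovery tests therefore demonstrate the fitting machinery is
correct and calibrated *within the model family*, not that real traces
identify the constants this cleanly.

## Fitting and identifiability

The lactate→RFU transform is affine per condition and profiled in closed
form inside the objective (`map_signal`); residuals are normalized by each
trace's centred energy, making the objective invariant to the arbitrary RFU
scale. Fitting is multi-start bounded least squares (scipy `trf`) in
log10-parameter space; starts are drawn log-uniformly within the bounds
from the seeded generator, so fits are deterministic given (dataset,
bounds, n_starts, seed). Finite-difference steps are fixed at 1e-4 in
log-space — well above the integrator's error floor, which otherwise turns
the numerical gradient into noise and stalls the optimiser. The triplicate
mean is the fitting target; the triplicate scatter is not used as a weight.

Because the gain is profiled away, a single lactate trace constrains only
trajectory *shape*. Three consequences, measured on synthetic data:

* kf_Glc (the uptake timescale) is the dominant shape parameter and is
  identified sharply even at 3 % noise (composite kf_Glc·Capacity_Glc
  recovered within 10 %, typically within 3 %);
* kf_1 is structurally degenerate with kf_Glc — two first-order lags in
  series — and freeing both creates a ridge on which the degenerate fit can
  beat the truth under noise;
* kf_5 is amplitude-coupled: noise-free data pins it, 3 % noise lets it
  wander (trajectory errors of 10–20 %).

The recovery experiment defaults therefore free (kf_Glc, kf_5) on
noise-free data and kf_Glc alone on noisy data, and recovery is asserted at
the predicted-trajectory level. Joint fitting across all four conditions is
supported (and is the default when a dataset contains several conditions);
it tightens kf_5 somewhat but does not remove the amplitude degeneracy.

## Problem sizes in the shipped tests

Unit and acceptance tests run the full 350-sample grid everywhere. The
integration-oracle comparison uses one condition at step 1e-3 min; the
noisy-recovery experiment uses 20 seeded replicates of a triplicate
glucose-only plate with 3 starts per fit. These sizes were chosen to make
the whole suite a coffee-break run on a laptop while keeping every
statistical claim testable.

## Known limitations

* The model is phenomenological: single lumped constants stand for entire
  enzyme cascades, stoichiometry is 1:1, and no attempt is made to conserve
  carbon atoms, redox state or ATP.
* The glutamine amplification term saturates only through TCA-pool
  depletion; there is no explicit transporter saturation, so extreme
  Gln_ex values extrapolate linearly.
* At oligomycin doses above 1/i2 ≈ 8.8 the literal reaction-6 factor is
  negative and the ETC pool can decay; this matches the printed equations
  but is physically meaningless — use the clamp flag if it matters.
* The mapping between physical modulator concentrations (µM oligomycin,
  mM 2DG) and the model's 1–10 dose units is not defined anywhere; doses
  are fit parameters, not measurements.
* Absolute RFU levels in the synthetic data are arbitrary; only normalized,
  affine-calibrated comparisons are meaningful.
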