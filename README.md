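# glygln

Kinetic modelling of coupled **glycolysis and glutaminolysis**, built around
the kind of real-time extracellular-acidification (ECAR) assay used to
monitor glycolytic flux in live cells.

A pH-sensitive plate-reader assay reports medium acidification — dominated
by lactate export — every 0.34 min over a 2-h run. That single extracellular
signal hides the intracellular story: how glutamine feeds the TCA cycle,
pulls pyruvate into the mitochondria and away from fermentation, and how
modulators (oligomycin, 2-deoxyglucose) reroute the fluxes. `glygln`
implements a compact compartmental ODE model of that network, simulates the
assay's standard conditions, generates realistic synthetic plate-reader
datasets, and fits rate constants to kinetic traces.

## The model

Ten dynamic species in three unit-volume compartments — medium (Glc_ex,
Gln_ex, Lac_ex), cytosol (Glc, Pyr, Lac, Gln), mitochondria (TCA, ETC,
CellComponents) — linked by nine reactions with first-order mass-action
rate laws (time in minutes, concentrations in model units nominally equal
to µM; Glc_ex = 7500 represents 7.5 mM glucose):

| # | Reaction | Net rate |
|---|----------|----------|
| 1 | Glc_ex → Glc | kf_Glc · Glc_ex · Capacity_Glc |
| 2 | Glc ⇌ Pyr | kf_1 · Glc · (1 + Oligo·i2 − 2DG·i1) − kr_1 · Pyr |
| 3 | Pyr ⇌ Lac | kf_2 · Pyr − kr_2 · Lac |
| 4 | Lac ⇌ Lac_ex | kf_3 · Lac − kr_3 · Lac_ex |
| 5 | Pyr ⇌ TCA | kf_4 · Pyr · (Capacity_M − TCA) − kr_4 · TCA |
| 6 | TCA → ETC | kf_5 · TCA · (1 + Gln/10) · (1 − Oligo·i2) |
| 7 | TCA → CellComponents | kf_6 · TCA |
| 8 | Gln → TCA | kf_7 · Gln |
| 9 | Gln_ex → Gln | kf_Gln · Gln_ex · Capacity_Gln |

The capacities (200/100/50) and modulator doses are constant boundary
factors. Every reaction converts one unit of substrate into one unit of
product, so the total pool is conserved — a built-in integration check.
The `(1 + Gln/10)` term makes intracellular glutamine amplify oxidative
output (reaction 6), which is how glutamine competes lactate away;
oligomycin suppresses that same flux while stimulating glycolysis, and
2-deoxyglucose throttles reaction 2.

A calibrated reference rate-constant set is shipped
(`glygln.reference_parameters()`), tuned so that the simulated assay
behaviours match the measured ones: glucose-only lactate plateaus at
~83 min, glutamine roughly halves final lactate while ETC output overtakes
it, oligomycin at dose 8.7 restores lactate to the glucose-only level, and
2-deoxyglucose at dose 9.9 suppresses it with a slow glutaminolysis-fed
rise in the second hour.

## Worked example

```python
import glygln as g

k = g.reference_parameters()
trajectories = g.run_assay_conditions(k)   # the four standard conditions
for name, traj in trajectories.items():
    stats = g.summarize(traj)              # plateau onset of Lac_ex
    print(f"{name:18s} Lac_ex={traj.final('Lac_ex'):7.1f}"
          f"  ETC={traj.final('ETC'):7.1f}"
          f"  onset={stats.plateau_onset_min:6.2f}")
```

```
glucose_only       Lac_ex= 3314.1  ETC= 1755.8  onset= 82.96
glucose_glutamine  Lac_ex= 1518.7  ETC= 6088.0  onset= 88.74
plus_oligomycin    Lac_ex= 3360.0  ETC= 2545.3  onset= 73.78
plus_2DG           Lac_ex=  124.7  ETC= 1113.6  onset=115.94
```

Reading these numbers: with glucose alone, lactate dominates and its
plateau begins at 82.96 min (sample 244 of the 0.34-min grid). Adding
glutamine cuts final lactate to 46 % of the glucose-only value while ETC
output quadruples — the shift from fermentation to oxidative metabolism.
Oligomycin (dose 8.7) brings lactate back to within 1.4 % of the
glucose-only level, yet ETC still exceeds it, showing the two overlapping
assay readouts hide different flux states. 2-deoxyglucose (dose 9.9)
collapses lactate to 3.8 % of the glucose-only level; what little appears
late comes from glutamine carbon leaking back out of the mitochondria.

The same pipeline is scriptable from the shell:

```sh
glygln simulate --condition all --out-dir out/        # tidy trajectory CSVs
glygln generate --seed 1 --out plate.csv              # synthetic plate data
glygln fit --plate plate.csv --free kf_Glc --out-dir fit/
glygln sweep --quantity dose_oligomycin --out sweep.csv
glygln export-sbml --out model.xml                    # validated SBML L3
```

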