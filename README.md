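# reefshield

Carbonate-budget accounting for shallow coral reefs, decadal projections of
*Acropora palmata* restoration, and post-processing of shoreline
total-water-level (TWL) tables — a reusable pipeline for reef ecologists and
coastal-hazard analysts asking whether a degraded reef crest can keep pace
with sea-level rise, and how much outplanting it would take to change the
answer.

## The model

**Carbonate budget.** For each surveyed site, gross carbonate production
(kg CaCO₃ m⁻² y⁻¹) is the sum over calcifying taxa of planar percent cover ×
a taxon calcification rate × (for corals) a rugosity correction factor.
Four bioerosion components are subtracted: parrotfish grazing (species-,
size- and life-phase-specific individual rates × belt-transect densities,
averaged over two belts), urchin grazing (a test-size → rate relationship ×
densities, scaled by a 0.57 sediment-reingestion factor), and endolithic
macro- (0.4 kg m⁻² y⁻¹) and micro-bioerosion (0.27 kg m⁻² y⁻¹) acting on
dead-coral substratum. Net production converts to a vertical framework
accretion rate through the cover-weighted mean coral skeletal density

&nbsp;&nbsp;&nbsp;&nbsp;*D·ᵢ* = Σₙ (*xₙ*/*Xᵢ*) · *dₙ*,

(default 1670 kg m⁻³ for net-erosional sites), and net-positive sites earn a
sediment/void credit reflecting Holocene reef-core composition
(*sed*/*void*/*frame* = 33/18/49 % of linear depth):

&nbsp;&nbsp;&nbsp;&nbsp;*Aᵢ* = *Fᵢ* · (1 + *sed*/*frame* + *void*/*frame*),&nbsp;&nbsp;*Fᵢ* = net/*Dᵢ*.

**Restoration projection.** A cohort of N outplants established in 2030
grows isometrically at 196.21 cm² y⁻¹ per colony, surviving each decade with
probability *sₖ* = 0.60 · *m*^(k−1), where *m* is 1.00 (fixed), 0.95
(increasing climate impacts) or 1.05 (decreasing impacts); added cover is
N × surviving fraction × colony area / 166,407 m² of reef-crest habitat.
Restoration-scenario budgets add ΔC × 29.07 kg m⁻² y⁻¹ (the measured,
rugosity-free *A. palmata* calcification rate) to gross production, and the
resulting accretion rate is compared with tabulated sea-level-rise scenarios
(keep-pace margin = cumulative accretion − cumulative rise).

**Flooding.** Externally computed shoreline TWL tables (storm × sea-level
offset) are linearly interpolated at restoration-adjusted sea levels,
max(SLR − elevation gain, 0) — clamped at the +0.0 m scenario — and
summarised alongshore with root-sum-square combination of TWL and
elevation uncertainties.

A synthetic-data module generates censuses (multinomial point counts,
Poisson fish/urchin counts), growth assays (linear trajectories + Gaussian
noise) and TWL tables with known ground truth, so the entire pipeline is
testable without field data.

## Worked example

```python
import numpy as np
from reefshield import (default_rate_table, site_budget, aggregate_zones,
                        cover_from_points, restored_budget, keep_pace,
                        default_slr_scenarios)
from reefshield.synthetic import SynthParams, gen_census

rates = default_rate_table()
sites, truth = gen_census(SynthParams(seed=42))          # 54-site survey
results = [site_budget(s, rates) for s in sites]
zones = aggregate_zones(results, sites)
overall = zones[zones.sector == "all"].iloc[0]
print(f"mean accretion potential: {overall['accretion_potential_mean']:.2f} "
      f"+/- {overall['accretion_potential_se']:.2f} SE mm/y")

restored = [restored_budget(r, cover_from_points(s), 0.30, rates)
            for r, s in zip(results, sites)]
mean_restored = float(np.mean([r.accretion_potential for r in restored]))
print(f"restored (+30% A. palmata) accretion: {mean_restored:.2f} mm/y")
```

Output:

```
mean accretion potential: -1.61 +/- 0.11 SE mm/y
restored (+30% A. palmata) accretion: 7.81 mm/y
```

The synthetic reef is net-erosional (bioerosion dominates on ~degraded
Caribbean fore reefs), and a +30 % *A. palmata* scenario flips it strongly
accretionary. Feeding the restored rate to the keep-pace analysis:

```
2100 Low               rise 0.36 m  margin +0.30 m  keeps pace: True
2100 Intermediate-Low  rise 0.52 m  margin +0.14 m  keeps pace: True
2100 Intermediate      rise 1.06 m  margin -0.40 m  keeps pace: False
```

The population model's headline numbers print from the CLI too:

```sh
$ reefshield population --n-outplants 500000 --out traj.csv
peak added cover: 42.4%
```

i.e. 500,000 outplants under fixed 60 % decadal survival peak at +42.4 %
added cover in 2050.

## Command line

`reefshield` subcommands: `validate`, `budget`, `project-bathy`, `growth`,
`population`, `restore`, `keep-pace`, `flood`, `simulate`, `run`
(full pipeline from a YAML config). See `reefshield --help`.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
what the synthetic generators do and do not emulate, and known limitations.
Shipped parrotfish/urchin rate values are documented placeholders — supply
a project rate table (YAML) for real analyses.
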