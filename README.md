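# atpwaste

Tools for analyzing *Escherichia coli* physiology under **enforced ATP
demand** — the metabolic-engineering regime in which the soluble
F1-subunit of the FoF1-ATP synthase is overexpressed so that the cell
wastes ATP and compensates with a higher glycolytic flux.

The package is aimed at systems biologists and metabolic engineers who
want to study (or re-analyze) the characteristic **biphasic response of
glucose uptake to rising ATPase expression**: uptake first increases with
demand, peaks at an intermediate expression level, and then collapses
below wild-type levels when ATP becomes too scarce to fuel
phosphofructokinase (PFK).

## What is inside

* **Kinetic model** (`atpwaste.model_core`, `atpwaste.kinetics`,
  `atpwaste.simulate`) — an ODE model `dx/dt = N v(x, p)` of anaerobic
  central fermentative metabolism (33 metabolites, 28 reactions: PTS
  glycolysis, the mixed-acid branches, anaplerosis/reductive TCA, growth,
  maintenance, and a tunable ATPase drain) built on convenience kinetics
  with multiplicative allosteric terms. PFK carries the mechanism at the
  heart of the analysis: ATP is a substrate, ADP an allosteric activator,
  so its rate is biphasic in the ADP/(ATP+ADP) ratio. Two model versions
  are provided; version 2 adds an ATP-dependent PFL capacity term and a
  pyruvate inhibition of pyruvate kinase. Steady states are found by
  stiff integration plus a Newton polish on the moiety-reduced system, and
  `scan_atpase` traces the response curves over vmax_ATPase ∈ [0, 85]
  mmol/gDW/h by continuation.
* **Metabolic control analysis** (`atpwaste.mca`) — flux control
  coefficients C^J_e = (e/J) dJ/de from the control-matrix relations (with
  a finite-difference cross-check), plus Monte Carlo sampling of the
  Michaelis constants over two orders of magnitude that *preserves the
  reference steady state* (each vmax is rescaled so the reaction
  reproduces its reference rate), giving FCC distributions and
  sign-dominance summaries.
* **Metabolic flux analysis** (`atpwaste.mfa`) — SD-weighted
  reconciliation of measured exchange rates onto the stoichiometric cone,
  LP maximization of the ATP-maintenance (ATPM) pseudo-flux, and the
  ATPase-flux estimate `r_ATPase = ATPM(strain) − ATPM(control)`.
* **Fermentation arithmetic** (`atpwaste.rates`) — growth rates from
  ln-biomass regression, specific rates for growing
  (`r_M = µ·Δc_M/Δc_X`) and growth-arrested (`r_M = Δc_M/X_av/Δt`)
  cultures, yields by regression, percent changes, cumulated carbon
  yields.
* **Synthetic data** (`atpwaste.synthetic_data`) and bundled measured
  rate/yield tables (`atpwaste.datasets`) for wild type, the low/medium/
  high-copy ATPase strains with their controls, and the HC-ATPase
  overexpression variants (pfkA/pflB/pgk).
* A thin CLI: `atpwaste synth | rates | mfa | scan | mca | report`.

## Worked example

```python
import numpy as np
from atpwaste import build_default_model, scan_atpase

model = build_default_model("v1")
print(model.n_metabolites, model.n_reactions)   # 33 28

scan = scan_atpase(model, np.arange(0, 86, 1.0))
pts = scan.flux_curve("PTS")
print(f"uptake: {pts[0]:.2f} -> max {pts.max():.2f} "
      f"at vmax={scan.grid[pts.argmax()]:.0f} -> {pts[-1]:.2f}")
print(f"energy charge: {scan.energy_charges[0]:.3f} -> "
      f"{scan.energy_charges[-1]:.3f}")
```

prints

```
33 28
uptake: 13.64 -> max 15.42 at vmax=25 -> 10.33
energy charge: 0.879 -> 0.326
```

i.e. glucose uptake (mmol/gDW/h) rises from its wild-type value to a
maximum at an intermediate ATPase expression and then falls below the
wild-type level, while the adenylate energy charge declines
monotonically — the biphasic signature. The ATP-hydrolysis flux itself
peaks at an interior expression level (16.75 mmol/gDW/h at vmax = 53):
the strain with the most ATPase does *not* hydrolyze the most ATP.

The bundled strain-comparison arithmetic:

```bash
atpwaste report --out report.json
```

reports, e.g., for anaerobic growth a +16.6 % (low-copy) and +17.8 %
(medium-copy) uptake gain over the controls, a −60.3 % collapse for the
high-copy strain, a cumulated product-carbon yield of 0.93 mol C/mol C
for the low-copy strain, and an estimated enforced ATPase flux of
25.45 mmol/gDW/h for the medium-copy strain.

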