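# Methods

## The kinetic model

### Network

The model describes anaerobic growth of *E. coli* on glucose with the
mixed-acid fermentation pattern. It contains 33 metabolites and 28
reactions. 25 metabolites are ODE states (µmol/gDW); 8 are clamped
boundary species: external glucose (`GLC_ex`), the five secreted products
(ethanol, acetate, formate, lactate, succinate), CO₂ and biomass. The
reactions:

* glycolysis: PTS (glucose uptake, PEP-coupled), PGI, PFK, FBA, TPI, GHD
  (glyceraldehyde-3-phosphate dehydrogenase), PGK, PGM, ENO, PYK;
* fermentative branches: PFL (pyruvate formate-lyase), LDH, PTA, ACK, and
  ADHE — the acetaldehyde/alcohol dehydrogenase pair lumped into one step
  because AdhE is a single bifunctional enzyme;
* anaplerosis and the partial TCA cycle: PPC, PCK, a lumped
  CS/ACO/ICDH step producing α-ketoglutarate and NADPH, MDH, fumarase
  (FHD), and fumarate reductase (FRD, with the menaquinone pool folded
  in), plus malic enzyme (MAE), soluble transhydrogenase (THD) and PEP
  synthase (PPS) as the minor NADPH/PEP shunts;
* energy bookkeeping: adenylate kinase (ADK), a lumped growth reaction
  draining precursors, ATP and NADPH, a maintenance drain (NGAM), and the
  ATPase reaction whose vmax is the expression knob of the analysis.

Five moieties are conserved and verified against the left null space of
the stoichiometric matrix: adenylate (ATP+ADP+AMP), NAD(H), NADP(H),
CoA/acetyl-CoA, and total reactive phosphate. Inorganic phosphate is a
state variable (not clamped) purely so that the phosphate balance closes;
no rate law is sensitive to it, because the pool is large and buffered in
vivo.

Units: concentrations µmol/gDW, fluxes mmol/gDW/h. The two systems meet
in exactly one place (`FLUX_TO_CONC = 1000` in `model_core`), where the
ODE right-hand side is formed.

### Rate laws

Every enzymatic step uses convenience kinetics — the generalized
reversible Michaelis–Menten law — times independent activation terms
`c^h/(Ka^h+c^h)` and inhibition terms `Ki^h/(Ki^h+c^h)`. Reversible
reactions carry a reverse-capacity ratio γ (= vmax_r/vmax_f); scaling the
single vmax scales the whole law, which is the degree-1 homogeneity the
control-coefficient summation theorem requires. Reactants without a Km
entry are treated as saturating; kinetic orders default to the
stoichiometric multiplicity and can be overridden (used where a lumped
reaction's stoichiometric coefficients are not kinetic orders, e.g.
growth).

Regulation (all structural choices, exposed in the config):

* **PFK** — the core mechanism: F6P and (Mg)ATP substrates, first-order
  ADP activation (Ka above the resting ADP level, so the activator term
  never saturates under physiological excursions), first-order PEP
  inhibition, and a *cooperative* (order 2) ATP term that is nearly
  saturated at the resting ATP concentration but steeply limiting once
  ATP collapses. The last point is what turns rising ATP demand from a
  stimulus (via ADP) into a brake (via ATP) and produces the biphasic
  uptake response.
* **PTS** — inhibited by G6P; this hexose-phosphate feedback is the relay
  that converts a faster PFK into a faster uptake.
* **FBA** — PEP inhibition; **PYK** — FBP activation.
* **PPC** — FBP activation (known allosteric control), which ties
  anaplerosis to the glycolytic state and shuts the C4 branch down when
  FBP is low; without it the oxaloacetate branch has no brake in the
  ATP-starved regime.
* **CS/ACO/ICDH** — product inhibition by α-ketoglutarate. AKG is
  produced only here and drained only by growth, so this (together with
  an AKG term in the growth kinetics) is what gives the pool a stable
  equilibrium when growth collapses.
* **NGAM** — a near-zero-order ATP drain (Km = 0.05 µmol/gDW, order 2
  rolloff only near depletion), the standard treatment of maintenance.
* **GROWTH** — convenience terms in ATP (order 2), pyruvate, acetyl-CoA,
  AKG and NADPH; the ATP dependence makes the growth rate collapse along
  the ATPase scan the way the measured strains do.
* **LDH** — second order in pyruvate with a high Km: it idles at resting
  pyruvate but provides a large reserve capacity once pyruvate
  accumulates, which carries the lactate switch of the high-expression
  regime.

Version 2 adds exactly two terms: the PFL capacity factor
`g(ATP) = g_min + (1−g_min)·ATP²/(Kg²+ATP²)` (g_min = 0.05,
Kg = 1.5 µmol/gDW), emulating the observed lower PFL abundance at low
energy charge, and a pyruvate inhibition of PYK
(`Ki = 3 µmol/gDW, h = 2`). Both vmaxes are re-anchored so versions 1 and
2 share the same reference steady state.

### Parameter provenance: anchored calibration

The original model's >100 fitted parameters are not re-fit here. Instead
the shipped default set (a *plausible* set, not the deposited one) is
constructed by `atpwaste.calibrate`:

1. fix a reference wild-type state — concentrations at printed values
   where available (PEP 0.27, F6P 0.91, FBP 9.74 µmol/gDW, adenylate
   ATP+ADP = 2.67 µmol/gDW, energy charge 0.88) and plausible anaerobic
   magnitudes elsewhere;
2. project the measured wild-type exchange rates onto the network's null
   space (SD-weighted least squares with irreversibility bounds) to get a
   reference flux vector with N·v = 0 exactly;
3. choose per-reactant saturation levels (σ = 0.5 for most substrates;
   near-equilibrium reversible steps get gross-to-net flux ratios ρ of
   3–10, which concentrates flux control in the irreversible committed
   steps) and the allosteric constants above;
4. back-compute every vmax so each law reproduces its reference flux at
   the reference concentrations.

The reference is therefore an *exact* steady state of the shipped model
(anchor residual ~1e-15), and it is dynamically stable. Rerunning
`python -m atpwaste.calibrate` regenerates `data/default_model.yaml`.

The growth stoichiometry (precursor drains ≈ 39 mmol C/gDW, 70 mmol
ATP/gDW, 8 mmol NADPH/gDW) is not printed in any source table; the ATP
coefficient lumps growth-associated maintenance and polymerization at a
literature-plausible Y_ATP ≈ 14 gDW/mol.

## Steady states and the ATPase scan

Steady states are found by a Newton polish in logarithmic coordinates on
the moiety-reduced system (independent rows of N selected by pivoted QR,
conservation constraints appended), with stiff LSODA integration bursts
(0.03 h, ×10 each round, capped at t_max = 50 h and 1500 steps per burst)
whenever the polish starts outside its basin. Convergence means
max |N v| ≤ 1e-8 mmol/gDW/h. Non-convergence yields a flagged state, not
an exception. If the ATP pool collapses below 1e-3 µmol/gDW during a
burst, the trajectory has fallen off the viable branch into the
ATP-depleted halt state and the point is flagged immediately rather than
chasing the slowly-relaxing boundary equilibrium.

`scan_atpase` walks vmax_ATPase from 0 to 85 mmol/gDW/h (default step 1)
by continuation from the previous converged state. The ADP-activation
clamp used for the counterfactual scan evaluates the PFK activation term
once at the vmax = 0 steady state and freezes it in all solves.
Biphasy is reported only if the discrete argmax is interior *and* the
terminal value lies at least 5 % below the maximum, so plateaus are not
flagged.

Version 1 holds a viable steady state over the whole scan. Version 2
undergoes a fold near vmax ≈ 74 mmol/gDW/h beyond which only the
metabolic-halt state remains; those grid points are reported flagged, and
the converged branch is biphasic just like version 1.

## Metabolic control analysis

Scaled FCCs are computed from numerically differenced elasticities via
`C = I − E L (N_R E L)^{-1} N_R` on the moiety-reduced system (the full
Jacobian is structurally singular because of the conserved pools), then
row-normalized by the reference fluxes. Rows belonging to fluxes below
1e-9 mmol/gDW/h are masked (the scaled coefficient is undefined). A
brute-force finite-difference route (re-solving steady states at
vmax·(1±1e-4)) serves as an independent cross-check and agrees to 1e-3.

The Monte Carlo analysis redraws every **Michaelis constant**
log-uniformly over two orders of magnitude (multiplier 10^u,
u ~ U(−1, 1)) and rescales each vmax so the reaction reproduces its
reference rate at the reference concentrations — all samples share the
exact reference steady state. Two implementation points matter:

* for reversible laws, γ is co-adjusted so the forward/reverse flux split
  at the reference is preserved; without this, redrawn Kms flip the
  direction of near-equilibrium reactions at the reference state and
  essentially every draw must be rejected;
* allosteric activation/inhibition constants are *not* redrawn: they are
  structural regulation, not saturation parameters. Sampling them
  degrades the demand→ADP→PFK relay in a sizeable fraction of draws and
  destroys the narrow, sign-dominant FCC distributions this analysis is
  meant to expose.

Reference states: wild type is vmax_ATPase = 0. For the
expression-strain references, the scan point whose uptake flux is closest
to the strain's measured uptake is used — on the rising branch for the
low-copy strain, anywhere for the medium-copy strain, on the declining
branch for the high-copy strain (vmax = 34 mmol/gDW/h for the latter with
the default v2 model). Monte Carlo runs use n = 200 samples, which bounds
the binomial error of a sign fraction at about ±3.5 percentage points;
finite enzyme-doubling predictions re-solve the steady state from the
reference with the chosen vmax doubled.

## Metabolic flux analysis

The MFA stoichiometric model reuses the kinetic network with the two
ATP-hydrolysis drains merged into a single ATPM pseudo-reaction
(ATP → ADP + Pi), so all unexplained ATP turnover lands in one LP
variable. Measured rate sets (glucose, five products, growth rate) are
first reconciled — minimize Σ((r−m)/SD)² subject to N·v = 0 and
irreversibility, solved with SLSQP on the row-independent system — and
then the ATPM flux is maximized by linear programming (HiGHS) with the
reconciled rates fixed. Growth-arrest scenarios fix the growth flux to
zero. The enforced ATPase flux of an overexpression strain is the
difference of maximized ATPM between strain and control; for the
high-copy overexpression variants the reference is the high-copy control
strain.

Because the shipped network is a reconstruction (the deposited 83-reaction
model is not printed anywhere), absolute ATPM values should be read at
order-of-magnitude precision; with the default growth energetics the
control strains come out at maintenance scale (~2–7 mmol/gDW/h) and the
expression strains 4–7× higher, reproducing the qualitative pattern of
the measured comparisons. Note that the measured rate sets are mutually
inconsistent (carbon over-recovery of a few mmol C/gDW/h), so the
reconciled scenario — and hence the ATPM optimum — depends on the SD
weighting; comparisons should always use the same weighting on both sides
of a subtraction.

## Rates, yields, and derived arithmetic

Growth rate: OLS slope of ln(biomass) vs time in the exponential window
(user-supplied; at least three points). Specific rates:
`r_M = µ (c_M,e − c_M,s)/(c_X,e − c_X,s)` for growing cultures and
`r_M = (c_M,e − c_M,s)/X_av/Δt` under growth arrest. Yields: regression
slope of Δc_M against Δc_Glc over the sampled points (biomass yield in
gDW/g using 0.18016 g/mmol glucose). OD420 is converted to biomass at
0.22 gDW/l per unit. Cumulated carbon yield:
`Σ Y_i·C_i / 6` with C = {ethanol 2, acetate 2, formate 1, lactate 3,
succinate 4}; note the convention is CO₂-free — formate carries its
carbon explicitly. Percent changes are rounded to one decimal and carbon
yields to two decimals at the reporting layer.

## Synthetic data

`synthetic_data` generates batch cultures from constant-specific-rate
mass balances (exponential biomass during growth, constant biomass under
arrest, closed-form concentration trajectories, glucose clamped at zero
on exhaustion). Noise mimics the instruments: multiplicative lognormal on
biomass (default σ = 2 %, OD-like) and additive truncated Gaussian on
concentrations (default σ = 0.1 mmol/l, HPLC-like). Generating values
default to the bundled measured strain tables.

What this does *not* emulate: rate drift within the window (real
specific rates are only approximately constant), correlated analytic
errors between metabolites, lag/decline phases, and the carbon
*consistency* of real fluxes — the generating tables themselves carry the
measured inconsistencies. Passing the recovery tests therefore
demonstrates correctness of the estimators and the pipeline plumbing, not
robustness to every failure mode of real fermentation data.

## Known limitations

* The default kinetic parameter set is anchored, not fitted to the full
  flux+metabolome data; quantitative curve shapes (peak position, depth
  of the collapse) are indicative, while the qualitative structure
  (biphasy, monotone energy charge, interior ATPase-flux maximum, control
  distribution signs) is the tested, robust content.
* Version 2's viable branch ends in a fold at high ATPase expression; the
  scan reports the halt region as flagged points instead of following the
  boundary equilibrium.
* The MFA network is far smaller than the deposited 83×54 model;
  reconciliation adjustments and absolute ATPM values differ accordingly.
* No thermodynamic (Haldane) consistency is imposed on the reversible
  laws beyond direction conventions; no Mg speciation of the adenylates;
  GDP (a second PFK activator in vivo) is omitted.
* Fluxes below 1e-9 mmol/gDW/h have undefined scaled control
  coefficients and are masked rather than reported.
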