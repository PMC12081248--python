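# Methods

This note records the model structure, the defaults that matter, what the
synthetic data emulate, and the numerical and design choices behind
`hsctpbpk`.

## Whole-body model

Fourteen compartments: lung, liver, gut, kidney, muscle, adipose, skin,
brain, heart, bone, spleen, a lumped "rest", and arterial/venous blood.
All tissues are perfusion-limited (no permeability-limited organs): the
scenarios of interest concern systemic exposure, not tissue gradients.
Blood pools are treated as plasma-kinetic; every concentration in the
state vector is plasma-referenced, and organ outflow concentration is
A/(V·Kp).

Flows are fixed fractions of cardiac output (CO), with gut and spleen
draining into the liver (portal inflow) and the hepatic artery carrying
6.5% of CO, so first pass is gut then liver in series. Because the
fractions sum to one, venous return equals CO identically for every
individual — flow conservation is by construction, and the test suite
asserts it.

**Reference physiology.** Organ volumes/flows for a 73 kg, 176 cm,
30-year-old male are a curated reference-human table
(`data/reference_physiology.yaml`, version 1). Volumes scale linearly with
body weight (brain with exponent 0.25, reflecting its relative
preservation in children), CO scales as W^0.75, and females get
muscle ×0.85, adipose ×1.30, CO ×0.92. Pediatric enzyme activity is a
piecewise-linear ontogeny multiplier per enzyme (default 1.0 at all ages);
only GSTA1 ships a non-trivial curve (1.3 below age 2 declining to 1.0 by
age 12), which reproduces the faster weight-normalized busulfan clearance
of children.

**Partition coefficients.** Kp is computed uniformly from logP, f_u and a
tissue-composition table in the Poulin–Theil style: lipid term
P·(f_nl + 0.3·f_ph) plus aqueous term (f_w + 0.7·f_ph), normalized to
plasma, times f_u/f_u,tissue with tissue binding assumed at half the
plasma binding strength. Adipose instead uses the vegetable-oil:water
partition log P_vow = 1.115·logP − 1.35 with no tissue-binding
correction; without this standard adjustment moderately lipophilic drugs
acquire fat Kp in the tens and week-long artifactual terminal phases.

**Clearance.** Pathways are enzyme-resolved: a linear pathway contributes
CL_int,organ = CL_int,specific · E(t) · w_organ · V_organ (specific units:
µL/min per µmol enzyme), a saturable one a Vmax(E)·Cu/(Km+Cu) term in
unbound µM. Because elimination draws on the organ outflow concentration
inside the flow network, hepatic clearance follows the well-stirred model
exactly in the linear limit — the acceptance suite checks AUC = Dose/CL
against the closed form to 2% over a 3×3 (body size × CL_int) grid. Renal
clearance is referenced to arterial plasma (filtration-like), which makes
total clearance exactly hepatic + renal; the alternative
(kidney-outflow-referenced) differs by a Q_kidney correction that is
negligible for the shipped drugs but would break the closed-form oracle.

**Absorption and events.** Oral doses enter a gut lumen either as an
instantaneous bolus (first-order model) or through a Weibull dissolution
forcing 1 − exp(−(t/τ)^β); a first-order ka moves lumen drug into the gut
tissue, through gut CYP3A4, then the liver. Only f_abs of each dose is
absorbable; the remainder never enters the system and mass balance is
defined on the systemically available input. Fed-state modifiers multiply
the dissolution scale and f_abs (posaconazole suspension ships
f_abs ×2.7, inside the reported 2.5–3.0 fed:fasted band). iv boluses are
state jumps with integrator restarts; infusions are forcing terms.
mg/kg doses resolve against the individual's weight at simulation time.

**Interactions.** Reversible inhibition uses the standard factor
(Km+S)/(Km·d_Km + S·d_S) with d_Km collecting competitive/mixed/
non-competitive terms and d_S uncompetitive/mixed(α)/non-competitive
terms; multiple perpetrators add inside the denominators, inactivation
hazards add, induction effects add. The driver concentration is the
unbound liver outflow concentration for hepatic enzymes and the unbound
gut concentration for gut-wall enzymes, converted to µM via MW. Enzyme
pools become ODE states only where a mechanism-based inactivator or
inducer targets them; purely reversible inhibition leaves pools static.
Transporters (P-gp, OATP1B1/3, BCRP, MRP, BSEP) are modeled as
transporter-mediated clearance pathways inhibited through the same code
path. Auto-effects (phenytoin inducing its own CYP2C9 route) couple
naturally.

**Prodrug.** Fosaprepitant converts to aprepitant by first-order
hydrolysis (12 h⁻¹) in the blood pools, mole-preserving via the MW ratio;
assembling fosaprepitant without aprepitant in the system is an error.

## Numerical choices

LSODA with rtol 1e-6 / atol 1e-9 (configurable), integrating piecewise
between dose events. Output lands on a uniform grid (default 0.1 h;
scenario runs use 0.25–0.5 h) plus a geometric refinement just after every
event so the trapezoidal AUC resolves post-bolus mixing; halving the grid
changes AUC by <1%. The state at an event time is recorded pre-dose (the
trough convention) with the post-dose value an ε later. Mass balance —
input = in-system + eliminated + converted — closes to ~1e-6 relative on
the shipped library, against a 0.5% acceptance bound. AUC extrapolation to
infinity uses a log-linear terminal fit on the last stretch of the
profile. Steady state is flagged when successive dosing-interval AUCs
agree within 1%.

## Drug library

Thirteen YAML files carry physicochemistry, pathways, absorption,
interaction constants and TDM windows. The numeric constants are curated
literature-typical values — systemic clearances, bioavailabilities and
interaction potencies were set once to the scale of published clinical
values (e.g., busulfan CL ≈ 13 L/h, cyclosporine trough ≈ 100 ng/mL at
100 mg bid, voriconazole nonlinear via a 3 µM CYP2C19 Km) — and the test
suite treats them as fixtures, not ground truth. Two calibrations deserve
note:

* **k_deg = 0.0158 h⁻¹** (CYP turnover half-life ≈ 44 h) is the shipped
  default for all pools. Together with phenytoin's induction parameters
  (Emax 3.0, EC50 0.8 µM unbound — chosen at the scale of phenytoin's own
  unbound therapeutic exposure, which autoinduction holds near
  0.7–0.9 µM), chronic phenytoin induces CYP3A4 ≈2.4-fold and the pool
  re-enters 10% of baseline 9.5 days after discontinuation, inside the
  clinically cited 7–10 day window. This washout is why an inducer
  stopped at day −1 still depresses day-6 troughs.
* The busulfan AUC window ships as 900–1,350 µM·min (the majority
  convention; a 900–1,500 variant exists) and is fully configurable.

Predicted DDI magnitudes for the shipped constants are qualitatively
faithful (inhibitors raise cyclosporine troughs 1.5–4×, ordered NM < IM <
PM for voriconazole; phenytoin depresses co-medication exposure) but are
not calibrated to reproduce any particular published scenario table to
the decimal — per-drug in vitro constants vary widely across sources, and
the platform's contracts are the mechanistic closed forms, conservation
properties and orderings that the acceptance suite pins down.

## Scenarios and dose optimization

Day 0 is the first victim dose; perpetrator courses may start on negative
(pre-transplant) days and the whole calendar is shifted internally so the
integrator starts at the earliest event — metrics are invariant to a
common shift. The trough on day d is read at the end of calendar day d,
immediately before the next scheduled dose; interval AUC is taken over the
victim's dosing interval opening that day and reported in µM·min. Troughs
are reported in ng/mL. Dose optimization walks an ascending user-supplied
grid (clinically dosable amounts only) and returns the smallest candidate
whose population mean lies inside the window; an attainment-fraction
criterion (fraction of individuals in-window ≥ threshold) is available and
is never more permissive at the window edge.

When multiple drugs share a timeline, all perpetrator courses in the
scenario default to starting with the victim on day 0 unless given
explicit start/stop days.

## Populations and synthetic data

Population sampling draws one counter-based RNG stream per individual
index from a single integer seed, so populations are bitwise reproducible
and order-independent. Variability is independent log-normal
(median-preserving, geometric CV) per named parameter — weight, height,
cardiac output, or any enzyme's baseline expression; no correlation
structure is imposed, because the emulated study conditions report only
mean ± SD outputs. Phenotype frequencies assign genotype classes before
residual expression variability. The "Japanese" label selects 57 kg /
165 cm demographic means.

The synthetic-data module generates observed-like datasets by simulating a
known truth model and applying multiplicative log-normal noise
(σ = √ln(1+CV²)); it emulates digitized single/multiple-dose plasma
profiles with sparse sampling. It does not emulate inter-study
heterogeneity, assay LLOQ censoring patterns (an LLOQ cut is available in
the loss), covariate-structured variability, or real digitization error —
so passing recovery tests demonstrate estimator correctness under the
stated noise model, not robustness to real literature data. Printed-value
fixtures (the scenario trough table and the discussion-level busulfan and
fold-change numbers from the reference HSCT simulation study) carry
machine-readable source anchors and are used only for arithmetic
verification of the ratio pipeline.

## Fitting

The loss is the sum of squared log-concentration residuals (PK spans
decades); observations at or below the LLOQ are excluded. Optimization is
multi-start (Latin hypercube over the bounds, seeded) bounded Powell in
log-parameter space — derivative-free, robust to decade-scaled parameters
— returning the best start. Two-fold evaluation is inclusive at both ends
of [0.5, 2.0]; the Guest limits use L = (δ + 2(R−1))/R for R ≥ 1 and
reciprocal symmetry for R < 1, preserving the induction/inhibition duality
(the sub-unity branch is a package choice; the criterion is usually quoted
for R ≥ 1).

## Problem sizes

Default suite and acceptance-script sizes were chosen to exercise each
property at modest cost: population scenarios use n = 1–8 individuals
(variability off where the check is deterministic), the recovery study 20
replicates × 12 samples in the test suite and 8 replicates in the
acceptance script, monotonicity sweeps 5 dose levels, and the washout run
28 simulated days at a 0.5 h grid. Larger populations (the conventional
n = 100) run in minutes and change means by little when CVs are zero.

## Known limitations

* Perfusion-limited tissues only; no permeability-limited organs, no
  lymphatic or dermal/inhalation routes; metabolites are not tracked
  except the fosaprepitant→aprepitant conversion.
* One absorption model per compound per simulation run (taken from the
  first oral event's formulation).
* Enzyme-pool dynamics use the hepatic driver for gut expression too; a
  per-organ pool split would matter only for gut-selective inactivators.
* Blood:plasma partitioning is carried as a parameter but flows are
  plasma-referenced; strongly erythrocyte-partitioned drugs (tacrolimus)
  are modeled on the plasma scale with f_u chosen accordingly.
* No HSCT-specific pathophysiology (mucositis, hypoalbuminemia, GvHD
  organ dysfunction): the virtual individuals are healthy-volunteer-like,
  which matches how the underlying drug models were built and is the main
  caveat when reading absolute predictions clinically.
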