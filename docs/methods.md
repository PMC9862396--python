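# Methods

This note documents the model implemented in `tegopbpk`, its assumptions,
the numerical choices behind it, and what the bundled synthetic data can —
and cannot — demonstrate about real clinical data.

## The model

`tegopbpk` is a whole-body physiologically based pharmacokinetic (PBPK)
model of the potassium-competitive acid blocker tegoprazan and its major
metabolite M1 (desmethyl tegoprazan), with a drug–drug-interaction engine
for CYP3A4 perpetrators.

**Structure.** Both compounds distribute over twelve organ compartments
plus arterial and venous blood, linked by regional blood flows.
Distribution is perfusion-limited: for organ *i*,

    dA_i/dt = Q_i (C_art − A_i / (V_i · Kp_i / BP))

in blood-concentration terms, where Kp_i is the tissue-to-plasma partition
coefficient and BP the blood-to-plasma concentration ratio. Gut and spleen
drain into the portal vein and the liver receives hepatic artery plus
portal inflow, so gut-wall and hepatic first pass arise from the mass
balance instead of being imposed as fixed extraction factors.

**Absorption.** An oral dose enters the stomach undissolved. Dissolution
follows a Weibull schedule

    m(t) = 1 − exp(−ln 2 · (t/t50)^b),

parameterized so that m(t50) = 0.5 exactly: t50 is the time to 50%
dissolved (fasted 0.942 h, shape 0.990; fed 4.23 h, shape 0.502). The
implementation integrates the equivalent time-varying dissolution hazard
m′/(1−m), capped at 200 h⁻¹ to guard the integrable singularity at t = 0
for shapes below one. Undissolved and dissolved material transit a
stomach → duodenum → jejunum (×2) → ileum → colon chain with first-order
transit; dissolved drug is absorbed at rate Peff × effective area ×
luminal concentration (Peff = 1.16×10⁻⁶ cm/s). A meal raises gastric pH
to 5.5 and slows gastric emptying (multiplier 0.25), both relaxing
exponentially (half-life 0.75 h — a config entry; the underlying report
gives the behaviour but no constant), and switches the formulation to its
fed dissolution profile.

**Metabolism and excretion.** Four first-order CYP reactions eliminate
tegoprazan, with product-resolved intrinsic clearances (µL/min/pmol
enzyme): CYP3A4→M1 9.29×10⁻³, CYP3A4→other 0.236, CYP2C19→M1 0.0921,
CYP2C19→other 0.242. The reaction rate at a site is enzyme level ×
CLint × unbound site concentration, the latter approximated by
fu × A/(V·Kp) of the expressing organ (the approximation lives in one
place in the engine). CYP3A4 is expressed in liver and small-intestinal
mucosa,
CYP2C19 in liver only. Renal excretion of tegoprazan is a total plasma
clearance of 0.297 mL/min/kg acting on arterial plasma at the kidney.
M1 is produced stoichiometrically by the two →M1 reactions and eliminated
by a lumped total hepatic plasma clearance of 0.140 mL/min/kg; M1's own
CYP3A4-mediated elimination is deliberately not modelled, so DDI
predictions for M1 are out of scope.

**DDI engine.** Each enzyme pool turns over as dE/dt = Rsyn − kdeg·E with
Rsyn = kdeg × reference concentration. A mechanism-based inactivator adds
an irreversible loss kinact·I/(KI+I)·E; an inducer multiplies synthesis by
1 + Emax·I/(EC50+I). Perturbations apply to every expression site of the
target enzyme. The perpetrator concentration I(t) (unbound plasma) comes
from a closed-form one-compartment oral model or a forcing table — the
victim-side turnover mechanism is the scientific content here, and
re-implementing full whole-body perpetrator models is out of scope. The
same unbound systemic concentration drives hepatic and gut enzymes (a
simplification; enterocyte exposure during absorption is higher in
reality).

## Parameters that matter

| Parameter | Value | Units | Origin |
|---|---|---|---|
| logP (both compounds) | 1.75 | – | published model estimate |
| fu, tegoprazan / M1 | 8.7 / 1.0 | % | literature |
| CLint (4 reactions) | above | µL/min/pmol | published model estimates |
| Renal plasma CL | 0.297 (1.31 L/h at reference) | mL/min/kg | literature |
| M1 hepatic plasma CL | 0.140 | mL/min/kg | fitted value |
| Weibull fasted / fed | 0.942 h, 0.990 / 4.23 h, 0.502 | – | fitted values |
| kdeg liver / gut | 0.019 / 0.030 | 1/h | literature-typical turnover; not printed in the source, so DDI magnitudes must be read together with this choice |
| Enzyme abundances | 4.042 / 1.052 / 1.121 | µmol/L | calibrated (below) |
| Clarithromycin KI, kinact | 5.49 µM, 2.52 h⁻¹ | – | literature (in vitro HLM) |
| Rifampicin Emax, EC50 | 9.0, 0.34 µM | – | literature |

## Calibration

Enzyme abundances are not published; what is published is the pathway
split of an oral dose: 71.6% via CYP3A4, 20.2% via CYP2C19, 7.82% renal
(91.8% hepatic in total). Two analytic identities make the calibration
nearly closed-form:

* within an enzyme, the product split equals the CLint ratio exactly
  (first-order kinetics) — e.g. 71.6 × 0.00929/0.2453 = 2.71% to M1;
* between enzymes, elimination shares are proportional to
  abundance × total CLint, so the abundance ratio is
  (fm₁/fm₂)·(ΣCLint₂/ΣCLint₁) ≈ 4.83.

`calibrate_enzyme_abundance` wraps this in a short fixed-point iteration
on full simulations: each enzyme's abundance is scaled by a common factor
across its sites until the simulated enzyme:renal elimination ratios match
the targets (typically 3 iterations). Targets are interpreted as shares of
the *eliminated* drug, so the ~1% of dose lost fecally rescales all
pathways alike rather than making the targets infeasible. The bundled
abundances are this calibration's output at the reference individual; the
hepatic CYP3A4 level (4.04 µmol/L) lands near literature liver
concentrations (~4.3 µmol/L), which we read as support for the overall
clearance scaling.

**Reference individual and the renal-clearance anchor.** The steady-state
AUC of a linear oral model is identically f_renal·Dose/CL_renal. The
published trio (7.82% renal, 2994.4 ng·h/mL at 50 mg daily) therefore
pins CL_renal at 1.31 L/h — the absolute value quoted alongside
0.297 mL/min/kg, corresponding to a 73.5 kg adult. The package's reference
individual is that 73.5 kg adult, and the headline simulations use it; at
a literal 50 kg body with per-kg scaling the same mass balance would force
an AUC near 4350 ng·h/mL, which no choice of the remaining parameters can
reconcile with the published exposure.

**Physiology and distribution substitutions.** Organ volumes, flows and
tissue compositions are a bundled self-consistent reference-adult table
(volumes scale linearly with weight, flows with weight^0.75). Partition
coefficients use a Poulin–Theil-type tissue-composition method (a
Berezhkovskiy-style variant is selectable; the method name is recorded in
every result, and per-organ overrides are supported). The blood-to-plasma
ratio is computed from erythrocyte partitioning,
BP = 1 − Hct + Hct·fu·K_rbc,u ≈ 0.58 for tegoprazan — typical for a
highly protein-bound drug. These substitutions preserve clearances and
AUCs (which the calibration anchors) but not necessarily peak
concentrations: the model's Cmax runs ~40% below the published values,
consistent with a somewhat too-large distribution volume from the
substituted Kp method. AUC-type quantities are therefore the meaningful
outputs; Cmax values should be read qualitatively.

**Colonic absorption** is enabled by default (with a 5-fold smaller
effective-area amplification than the small intestine). With the fed-state
Weibull profile (t50 4.23 h) a colon that absorbs nothing would send
roughly half the fed dose out fecally, contradicting both the
near-complete absorption implied by the published mass balance (99.6% of
dose accounted for by elimination pathways) and the clinical absence of a
food effect on AUC. It can be disabled per run (`colon_absorption=False`).

## Numerical choices

* Internal units: µmol and hours; ng/mL at the interface via the
  molecular weight (µmol/L × g/mol = ng/mL).
* Stiff integration (LSODA), rtol 1e-8 / atol 1e-10 µmol by default;
  integration restarts at every dose and meal event. Iterative work
  (fitting, calibration, sensitivity) uses rtol 1e-6 / atol 1e-9.
* Multiple doses share one dissolution clock: the Weibull hazard is reset
  at each dose. Residual undissolved material from an earlier dose then
  dissolves on the newer dose's schedule — negligible for fasted daily
  dosing (dissolution completes within hours) and an accepted
  approximation for fed regimens.
* Perpetrator modifiers are tabulated on a 0.05 h grid per run; enzyme
  turnover time constants (tens of hours) make this lossless in practice.
* Steady state is declared when the interval AUC changes by <1% between
  successive dosing intervals.
* NCA uses linear-up/log-down trapezoids; λz is the log-linear tail fit
  (last 3–8 points) with the best adjusted R²; AUC_inf = AUC_last +
  C_last/λz, flagged absent when no declining tail exists.
* Fitting minimizes summed squared log10 residuals (the same geometry as
  the MRD metric), Nelder–Mead on log10-transformed parameters —
  deterministic given data and spec.

## The synthetic-study generator

`synthetic.training_suite_designs` emulates a 19-study corpus (10
training / 9 test): doses 50–400 mg, single and repeated regimens, fasted
and fed arms, dense early sampling, proportional log-normal residual error
(default CV 20% — a standard stand-in; the real corpus's digitization
error structure is unknown), LLOQ censoring with logged counts, and one
interaction-layout arm (tegoprazan + clarithromycin) carrying only the
parent series, mirroring how such arms exclude the metabolite from
training.

What passing tests on these data show: the estimation machinery recovers
generating parameters under the stated noise, the metrics behave per their
definitions, and the pipeline is internally consistent. What they cannot
show: agreement with real digitized concentration data (the published
MRD/GMFE/two-fold values are not reproducible without those data and are
deliberately not targets), inter-study heterogeneity, or real residual
error structure.

**Identifiability.** From tegoprazan + M1 plasma profiles alone the
CYP3A4/CYP2C19 attribution of clearance is structurally unidentifiable —
both enzymes act in the same compartment and the M1 they form is
indistinguishable. The recovery study therefore uses the minimal
identifiable set: one single-dose arm plus the interaction arm (with both
analytes), in which clarithromycin's near-complete CYP3A4 suppression
separates the enzymes. This mirrors how the original parameterization
leaned on ISEF-corrected in vitro values to anchor the split.

## Known limitations

* Cmax under-prediction (~40%) from the substituted distribution model;
  see above.
* The clarithromycin steady-state AUC fold (≈2.8 at the bundled
  parameters) under-predicts the published 4.54, mainly because the
  simplified one-compartment perpetrator and the modest gut-wall CYP3A4
  first pass (~5% of dose) understate intestinal interaction; the
  rifampicin fold (≈5.6 vs 5.26–5.71) is on target. The engine-level
  limits (null perpetrator, complete-knockout identity, monotonicity in
  kinact/Emax) are exact and tested.
* No pH-dependent solubility feedback (tegoprazan's own acid suppression
  on repeated dosing is not modelled), no saturable metabolism, no
  transporters, no enterohepatic recirculation, no DDI on M1 elimination.
* Population variability is independent log-normal on a configurable
  parameter list (default: enzyme abundances), not a full anthropometric
  covariance model.
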