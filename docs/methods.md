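# Methods

## Overview

`renaltwin` couples three model layers to run in-silico ("virtual") trials
of renal waveform biomarkers:

1. **1D systemic + renal arterial network.**  Cross-sectionally averaged
   mass/momentum equations per vessel segment over a rooted tree of 147
   segments: a 75-segment systemic tree with 27 lumped R-C-R outlets, plus
   two renal trees (per kidney: 1 main, 5 segmental, 10 interlobar, 20
   arcuate arteries).
2. **0D renal microcirculation.**  Each of the 40 arcuate arteries feeds a
   microvascular bed of 650 interlobular arterioles in parallel, each
   supplying 60 nephrons.  A nephron is a fixed bridge-topology resistor
   network (afferent arteriole; glomerular capillary → efferent arteriole;
   glomerular filter → renal tubule → ureter; reabsorption shunt; peritubular
   capillary) solved by nodal analysis.  Arteriolar/tubular resistances are
   Hagen–Poiseuille (R = 8μL/πr⁴); the capillary/filter/reabsorption/
   peritubular/ureter resistances are literature-ratio constants.
3. **Population and disease parameterisation.**  Multiplicative factors on
   every mechanical parameter encode sex, age group (20–29 … 70–79),
   Gaussian inter-individual variability, and the disease states
   DM+HTN → DKD / HKD.

## 1D solver

* Tube law `P = P_ref + (β/A₀)(√A − √A₀)` with `β = √π·E·h/(1 − ν²)`.
  Default Poisson ratio ν = 0, so the reference wave speed is exactly the
  Moens–Korteweg speed `c₀ = √(E·h/(2ρ·r₀))` (ρ = 1060 kg/m³).  The
  reference radius is taken at the diastolic pressure of the inflow
  (`ref_pressure`, default 75 mmHg).
* Friction assumes a power-law axial velocity profile with exponent γ = 9
  (source term −2(γ+2)πν Q/A).
* MacCormack predictor–corrector on the conservative (A, Q) form, uniform
  per-vessel grids (`target_dx` 10 mm default, ≥ 3 cells per vessel; the
  trial configuration uses 13 mm / ≥ 2 cells, which changes brachial
  pressures by < 0.3 mmHg).  Global time step from the CFL bound with a
  velocity headroom margin.
* Junctions (any number of daughters) solve, per time step, a Newton system
  enforcing mass conservation, total-pressure continuity and the outgoing
  characteristic invariants `W = u ± 4c`; terminals couple to R-C-R
  windkessels with a semi-implicit compliance update.  The proximal
  windkessel resistance is the terminal vessel's characteristic impedance
  (reflection-minimising split), the remainder distal.
* Cycles are iterated (75 bpm; sin²-lobe aortic inflow with a small reverse
  wave at valve closure, scaled to the subject's cardiac output) until the
  inlet pressure trace changes by < 10⁻³ (relative L2 against the pulse
  pressure) between cycles.  An Aitken extrapolation of the slowly charging
  cycle-mean pressure is applied as a uniform pressure shift (at most
  twice), which roughly halves the number of cycles to periodicity;
  converged states can warm-start similar subjects.

## Reference network (packaged substitute)

Bespoke dimensional tables behind the reported reference haemodynamics are
not publicly available; the packaged tree (`data/systemic_75.yaml` + the renal-generation defaults) is a
substitute assembled from standard adult segment tables and **calibrated**
so the reference subjects reproduce the literature validation anchors: brachial ~118/79 mmHg and mean aortic pressure ~93 mmHg at 5.6
l/min (20–29 cell), ~17% of cardiac output to the kidneys (this is fixed by
the bed resistance 2.80×10¹⁰ Pa·s/m³ per arcuate), and segmental resistive
index levels and disease responses (healthy reference subjects land at
0.64–0.75 across cells).  Calibrated quantities: a windkessel
derating factor (0.84) absorbing distributed viscous losses, the terminal
compliance total (7.5×10⁻⁹ m³/Pa), wall-stiffness classes (aorta 350 kPa …
distal muscular 850 kPa at class-specific h/r), and the renal generation
radii (main 2.75 / segmental 2.0 / interlobar 1.3 / arcuate 0.85 mm).  The
arcuate radius sets the bed-coupling impedance split and thereby the flow
pulsatility (RI level) at the measurement sites; each model "arcuate
artery" stands for an arcuate plus its immediate branches, which is why its
effective radius is larger than a literal arcuate vessel.

## Microcirculation numbers

With the reference geometry the reduction chain gives: single nephron
2.67×10¹⁴, 60-nephron block 4.44×10¹², bed downstream of one arcuate
2.79×10¹⁰ Pa·s/m³, blood-side filtration fraction 0.076.  The diabetic
arteriolar edit (afferent diameter ×1.10, efferent ×0.93, R ∝ d⁻⁴)
**raises** the bed PVR by 1.4%; together with the 57% nephron loss the bed
PVR factor is 1.357, matching the tabulated diabetic renal factor 1.35.
The hypertensive 10% PVR increment corresponds to a 3.1% interlobular
lumen constriction (bracketed root solve).  GFR is one-way coupled: the
converged cycle-mean arcuate pressures drive the disease-edited bed solve
(venous side fixed at 5 mmHg, configurable); both the filtration fraction
and the absolute filter-branch flow (ml/min over 40 beds) are reported.
Note that this filtration fraction caps GFR near 70 ml/min (healthy) /
~50 ml/min (DM+HTN) at physiological renal blood flow — substantially
below clinically typical GFR, a direct consequence of the tabulated
component resistances.

## Population sampling

Factors compose as `sex(param) × age(param) × disease(param) ×
N(1, cv_subject) × N(1, cv_vessel)`, the last drawn independently per
vessel (draws truncated below at 0.2× the mean).  The subject-level
component is essential: with purely per-vessel independent draws the noise
averages out over the 40 parallel renal beds and the cohort dispersion of
renal indices collapses.  Default CVs — subject level: CO 8%, viscosity 3%,
radius 3%, E 8%, wall 5%, PVR 11%, PVC 10%; per-vessel: 5% (2% length).
They are calibrated once against reported cohort dispersions (segmental RI
SD ≈ 0.04, GFR SD ≈ 10% of the mean).  Only the renal PVR sex ratios
(0.85 male / 1.15 female) are fixed by reported values; the other sex/age factor tables
are editable substitutes with literature-informed trends (stiffening
+12%/decade, CO −4%/decade, renal PVR +9%/decade, systemic +5%/decade).

Disease columns multiply on top (healthy → DM+HTN → DKD or HKD), and the
disease counterparts of a retained healthy subject reuse its sampled draws
(paired design).  Terminal PVR follows the printed columns (1.17 / 1.35 /
1.29 renal); blood viscosity (×1.20) enters only the 1D friction term since
the printed PVR columns already summarise the microvascular state.

## Inclusion filter

A healthy candidate is retained when brachial SBP and DBP lie within 2.575
reference SDs of the sex/age reference mean and the mean segmental RI lies
in [0.47, 0.80].  The original filter reference tables are unavailable; the
substitute uses the cell's own reference-subject pressures as means and
reference SDs of 1.9 / 1.4 mmHg — calibration constants chosen once so the
filter reproduces the reported ~26% inclusion rate under the default
sampling CVs.  They parameterise the filter's stringency, not a claim about
measurement error.

## Trial statistics

* AUC by the rank (Mann–Whitney) formula, ties counted ½.
* Linear log-odds model: unpenalised maximum likelihood on features
  standardised to the training split; a weak ridge (C = 10³) only if the
  unpenalised fit fails to converge (complete separation).  Decision
  threshold 0.5 for accuracy.
* Repeated stratified 70/30 holdout, 50 iterations, seeded.
* Combination search: full enumeration when the count per dimension is
  within the cap (default 5000), else seeded uniform sampling without
  replacement; top-100 combinations above AUC 0.8, per-biomarker frequency
  counting.  The "common" group excludes pressure- and PWV-derived
  biomarkers (area retained).
* Biomarkers per location (main/segmental/interlobar/arcuate): waveforms
  averaged over the generation's vessels per side, features extracted, then
  left/right averaged.  Panel: 5 quantities (flow, velocity, pressure,
  wave speed, area) × 5 features (systolic, diastolic, mean, acceleration
  slope, deceleration slope) + RI + PI = 27 names.
* End-diastole is the value at the next cycle's upstroke foot (clinical
  convention; global-minimum mode available); the foot is located by the
  intersecting-tangents rule (steepest upstroke tangent × diastolic
  baseline).  On smooth Gaussian-like upstrokes this convention places the
  foot at baseline + e⁻²·amplitude, which the surrogate tests use as a
  closed-form oracle.

## Surrogate cohorts

The synthetic generator emulates only the *statistical* structure the
analysis assumes — Gaussian parameter variation with class-conditional mean
shifts on a two-Gaussian-lobe waveform template.  A standardised shift δ on
a template parameter that is the sole source of variation yields a binormal
AUC Φ(δ/√2), which the full biomarker+trial pipeline recovers within 0.03
(δ ∈ {0.5, 1, 2}).  Passing surrogate tests therefore validates the
feature-extraction and classification stages, not the haemodynamics.

## Problem sizes

The reference trial conditions are a 24,000-subject population over 12
sex/age cells.
The packaged trial default is the scaled-down acceptance cell: 256 healthy
candidates in the 50–59 male cell (≈ 65 retained per class after the 26%
filter) at the coarse grid (13 mm, ≥2 cells/vessel, CFL 0.9), about 1.3 s
per subject on one core.  The number of candidates is the package's choice
of desk-scale problem size; all statistics scale up unchanged.

## Known limitations

* The renal geometry and sex/age tables are calibrated substitutes; results
  that depend on their exact values (absolute AUC levels of the DKD/HKD
  contrast, absolute GFR) differ from the reported results — measured here:
  DKD-vs-HKD AUCs ≈ 0.70 (PI), 0.78 (PI+RI), 0.83 (flow triplet) versus
  the reported 0.87/0.94/0.96, with identical qualitative structure (PI the
  top common univariate biomarker; proximal-to-peripheral decline of
  velocity/flow biomarkers; monotone gain up to 3 biomarkers).
* One-way 1D→0D coupling; no renal autoregulation, viscoelastic walls, or
  disease progression.
* The substitute aging tables reproduce the renal decline (renal blood
  flow −29% from 20–29 to 70–79, RI rising) but flatten the in-vivo rise
  of brachial systolic pressure with age; calibrating the healthy RI level
  to the disease-cohort anchors leaves the healthy cells ~0.03–0.05 above
  the in-vivo RI trend.
* The diabetic arteriolar edit raises bed PVR (+1.4%) in this circuit,
  whereas the reported effect is a 1% decrease — inconsistent with the
  tabulated component resistances (see the worked-values script).
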