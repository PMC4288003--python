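# Methods

## Model structure and assumptions

The body is ten anatomical compartments plus arterial and venous blood.
Lung, gut, spleen, kidney and rest-of-body are perfusion-limited: well
stirred, with venous outflow concentration `C_tissue * RB_P / Kp`.
Liver, muscle and adipose are permeability-limited: an extracellular
(vascular) space sits in the blood path and exchanges with an
intracellular space through a bidirectional passive diffusion clearance
acting on unbound concentrations (`fu_p * C / RB_P` on the blood side;
`fu_liver * C_IC` in liver, `fu_p / Kp * C_IC` in muscle and adipose, so
the passive equilibrium ratio equals the configured Kp).  Muscle and
adipose passive clearances are fixed ratios of the liver value (defaults
0.2 and 0.05).

The liver is divided into `n_liver_subunits = 5` serial pairs of liver
blood and liver tissue; total active uptake, passive diffusion and
biliary clearance are split equally across pairs.  The serial
arrangement makes hepatic extraction behave like a dispersion-limited
organ rather than a single well-stirred unit; with `n = 1` the model
reduces to the well-stirred limit (plasma AUC differs by a bounded
amount, reported in the test suite, not asserted equal).

Enterohepatic recirculation: each liver-tissue unit excretes
`CL_bile/n * fu_liver * C_IC` into a bile-duct compartment whose volume
is 0.318% of liver volume; the duct empties continuously into the GI
lumen at 350 mL/day (0.01458 L/h).  Gallbladder storage and
meal-triggered emptying are deliberately absent (continuous bile flow).
Lumen drug — initial oral dose and recirculated biliary drug alike — is
absorbed into the portal inflow of liver sub-unit 1 at `ka * FaFg *
X_lumen`; the remainder `ka * (1 - FaFg) * X_lumen` goes to an
unabsorbed (fecal) sink.  Two genuinely open structural choices were
resolved as follows: absorbed drug bypasses the gut tissue compartment
and enters portal blood directly (first-pass hepatic exposure is
essential for uptake-dependent oral PK; the gut compartment is
distribution-only), and recirculated drug shares the initial dose's
Fa·Fg split (one mechanism, no evidence for two).

Renal clearance acts on venous plasma (`CL_renal * C_ven / RB_P`),
matching the plasma-referenced convention of fitted and literature
values.  All kinetics are linear (no saturable transport), and mean
profiles are simulated — no inter-individual variability.

Internal units: amounts ng, volumes L, time h, concentrations reported
in ng/mL.  The shipped 70-kg reference physiology (cardiac output
390 L/h, liver 1.8 L with 87.1 L/h total blood flow of which ~73%
portal) is a documented package fixture.

## Genotype clearance algebra

`CL_act,tot = CL_act,OATP1B1 + CL_act,other`, with the OATP1B1 share
given by `f_OATP1B1` (pravastatin preset 0.83; rosuvastatin 0.5005 from
35% NTCP and 77% of the non-NTCP remainder).  The nongenotyped OATP1B1
clearance is the haplotype-frequency-weighted mean of per-variant
clearances with effective ratios `r_v = activity_ratio_v *
expression_mult_v` (presets: activity 0.81/0.35 for pravastatin and
0.82/0.15 for rosuvastatin for *1b/*15; expression 2/1; European
frequencies 0.56/0.26/0.18).  Intrinsic activity and expression are kept
as separate fields so the "no expression gain for *1b" re-analysis is a
one-field change.  *5 is merged into *15; diplotypes are homozygous
only; c.521TT/CC relabeling to *1a/*15 is a mapping utility, not baked
into the algebra.  The ethnic scalar (0.584 Japanese/Caucasian)
multiplies every active-uptake entry, including CL_act,other.

Exactness properties (enforced by tests): the frequency-weighted mean of
per-variant clearances reproduces the input mean to machine precision;
splitting is exactly complementary; scaling commutes with the variant
algebra; a variant with effective ratio 1 is indistinguishable from *1a
in clearance and in the full simulated profile.

## Numerics

The system is linear with piecewise-constant input, so two integration
routes exist: LSODA (stiff-capable, default rel_tol 1e-8 / abs_tol
1e-10 ng) and an exact matrix-exponential propagator over the output
grid (`method="expm"`), used by the fitting loop; the two agree to
~1e-7 relative and cross-check each other in the tests.  Dosing events
split the integration into segments; IV infusion is a constant venous
input over its duration (handled exactly in the expm route via an
augmented constant-input state).  States are clipped at zero only within
solver tolerance; larger negative excursions raise an error suggesting
tighter tolerances.

## Parameter estimation

The objective is the pooled sum of squared residuals of log
concentrations across all datasets (unweighted) — the natural scale for
profiles spanning two orders of magnitude.  The search runs in log10
parameter space ("nonlinear sampling" is interpreted as log-uniform
population initialization: clearances span orders of magnitude), with
differential evolution (rand/1/bin, population 15 per parameter,
mutation dithered 0.5–1, crossover 0.7, up to 120 generations by
default, followed by a local polish); failing candidate simulations
receive a penalty loss rather than crashing the search.  Fits are
deterministic given a seed; estimates within ~0.1% of a bound are
flagged as at-bound.

Residual bootstrap: log-scale residuals at the optimum are resampled
with replacement onto the fitted log-curves and each pseudo-dataset is
refit.  The default refit is a bounded trust-region least-squares start
at the point estimate — bootstrap replicates are local perturbations of
the optimum, and a full global search per replicate buys nothing at
desk-scale runtime; a reduced-budget DE refit (`refit="de"`) is
available where multimodality is suspected.  Intervals are 2.5/97.5
percentiles; replicates whose refit fails are dropped, and more than 20%
drops is an error.

The noncompartmental Fa·Fg cross-check uses `F_oral / F_h` with
`F_h = 1 - (CL_plasma - CL_renal) / RB_P / Q_h`.  A structural note:
with AUCs extrapolated to infinity this estimator is *exact* in the
model's topology (every blood stream entering the liver carries the
venous AUC, and recirculation amplifies IV and oral exposure
identically, so it cancels in the dose-normalized ratio).  The
documented overestimation under enterohepatic recirculation appears when
AUCs are computed over a finite clinical sampling window (24 h here):
recirculation lengthens the terminal tail, inflating the apparent plasma
clearance and deflating F_h.  With CL_bile = 0 the finite-window
estimate agrees with the generating Fa·Fg within 2%.

## Sensitivity analyses

Model sensitivities are 1% forward differences normalized to parameter
and output, `S(t) = [(y' - y)/y]/0.01`, on a 0.1 h output grid (plasma
or intracellular-liver concentration over a window — 8 h for the
pravastatin analysis, 24 h for rosuvastatin — or the plasma AUC as a
scalar); |S| >= 0.3 is flagged.  Time points where the output is zero
yield marked undefined entries.  A 0.1% central-difference oracle and a
Richardson step-halving check verify convergence.  The forward scheme's
first-order truncation is a real, quantified property: for exponential
output phases the relative error is ~|S| * h / 2 and for
reciprocal-dependence parameters (RB_P) the normalized curvature is ~2,
so flagged coefficients can deviate from the central oracle by slightly
over 1% relative (measured maximum 1.2% on the shipped pravastatin
analysis; absolute deviations stay below 0.005).

The in vitro ratio analysis perturbs an intrinsic activity ratio by 1%
with the expression multiplier held fixed (this keeps the *1b analysis
well-defined; perturbing the effective ratio instead is available by
perturbing the multiplier) and re-derives all per-variant totals from
the fixed nongenotyped CL_act,tot and fixed frequencies at each
fractional contribution f in [0.2, 1].  Both CL_act,OATP1B1 and
CL_act,other are re-derived at each f.  Because the algebra is
homogeneous in the total clearance, the coefficients are independent of
its value.  Holding the population mean fixed enforces a sum rule: the
frequency- and clearance-weighted sum of per-variant sensitivities to
any intrinsic ratio is exactly zero.  Coefficient magnitudes increase
monotonically with f; |S| >= 0.1 is flagged.

## Synthetic data

The generator emulates mean ± SD plasma profiles of clinical studies:
the model truth at a clinical sampling schedule, multiplied per time
point by lognormal noise with sigma = sqrt(ln(1 + cv^2)) (median
unbiased; log-residual SD equals cv to first order), averaged over
n replicates; genotype-stratified cohorts apply the variant prediction
first and noise each group independently.  Default cv = 0.2, within the
reported in vitro variability scale (CVs below 60%).  What it does not
emulate: between-study heterogeneity, sparse/irregular sampling,
below-LOQ censoring, heterozygote groups, covariate structure.  Passing
recovery tests therefore demonstrates identifiability and correctness of
the estimation machinery under the model's own assumptions, not
robustness to real-data pathologies.

Fixture compounds (`pravastatin_like`, `rosuvastatin_like`,
`fluvastatin_like`) carry the published genotype constants exactly, but
their clearance/absorption magnitudes are package fixtures chosen once
to give the characteristic shapes (early tmax ~0.7 h with mixed
renal/hepatic elimination vs. slow absorption, tmax ~3.5 h,
uptake-dominated; the fluvastatin-like fixture has unit *15 ratios, high
passive permeability and negligible renal clearance).  Dose regimens
follow the source studies: IV 9.9/8 mg with oral 19.2/40 mg for the
nongenotyped fits, oral 40/10 mg for genotyped cohorts.

## Problem sizes

Shipped analyses use 12-point clinical sampling schedules per arm, a
0.1 h simulation grid (0.02 h for AUC-based NCA), DE budgets of 60–120
generations, and 50–200 bootstrap replicates; these are the package's
default desk-scale settings and are recorded per run in the manifest.

## Known limitations

- Compartment topology and physiological values are a reconstruction of
  a standard whole-body arrangement; they are internally consistent and
  validated by conservation/limit tests, but not traceable to any single
  published parameter table.
- Linear kinetics only; saturable uptake, transporter induction and
  drug–drug interactions are out of scope.
- Heterozygotes and the *14 haplotype are not modeled; *5 is folded into
  *15.
- The bootstrap quantifies observation-noise uncertainty conditional on
  the model; structural uncertainty (e.g. the serial-liver count) is not
  propagated.
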