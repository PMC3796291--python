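# Methods

## Models

### Pharmacokinetics

Plasma kinetics are linear compartmental models per kg body weight: a depot
(first-order `ka`) or a zero-order input of fixed duration feeding a central
compartment (`V1`, clearance `CL`), optionally exchanging with one
peripheral compartment (`Q`, `V2`).  Concentrations are total plasma, in nM;
dose masses (mg/kg) are converted with a per-drug `nmol_per_mg` factor that
is a required configuration input (molar masses are not part of the printed
record; the generator uses 2286 nmol/mg for PF-03882845 and 2413 nmol/mg for
eplerenone, from the molecular weights 437.4 and 414.5 g/mol).
Bioavailability is fixed at 1: with oral data only, absolute F is not
identifiable and all parameters are apparent.

Repeated dosing reduces exposure for both compounds; this is modeled as
clearance induction: CL rises **linearly** from `cl_initial` to `cl_induced`
between 24 h and 168 h (Days 1–7) and is constant outside that window.  The
linear ramp is the simplest monotone interpolant between the two stated
plateaus and gives testable boundary behavior (Day 4 = the mean of the two
clearances).  The acute eplerenone model instead uses a dose-dependent
clearance `CL = θ₁·(30/dose)^pwr·exp(η)` with θ₁ the clearance at the 30
mg/kg reference dose.

Chronic model structures: eplerenone one-compartment, PF-03882845
two-compartment, both first-order oral.  Acute structures: PF-03882845
one-compartment first-order; eplerenone two-compartment with a 1-h
zero-order input into the central compartment (matching its observed Tmax).

**Numerics.**  Because the kinetics are linear, profiles are computed by
piecewise-analytic propagation: between events (dose times, infusion
starts/ends) the coefficients are constant and the exact matrix solution of
the 2×2 disposition system (eigen decomposition, exponential and constant
forcings solved in closed form) is used.  Across the induction ramp the
interval is cut into 0.5-h substeps with clearance taken at the substep
midpoint; since CL is linear in time, the midpoint rule integrates the
cumulative elimination exactly at substep boundaries.  The propagator agrees
with an LSODA reference at rtol 1e-11 to better than 1e-4 relative, and the
test suite checks it against a naive explicit-Euler integrator.

### Pharmacodynamics

Two scalar linear turnover systems:

* UACR (opaque units; the assay's albumin/creatinine units are never
  standardized in the source record):
  `dUACR/dt = Kin·[1 − Imax·C/(C+IC50)] − Kout·UACR`, initial value `uacr0`
  per animal.  The aldosterone-infused disease state is encoded as
  `uacr0 < Kin/Kout`, so the untreated trajectory rises toward `Kin/Kout`;
  sham animals sit at their own steady state.  Drive: total plasma
  concentration (potencies on the total scale; binding corrections applied
  afterwards in the TI table).
* Delta endpoints: `dΔ/dt = Kin,max·C/(C+EC50) − Kout·Δ`, `Δ(0)=0`.  Serum
  K⁺ uses total concentration; the acute urinary Na⁺/K⁺ endpoint uses the
  dimensionless drive `fu·C / IC50_invitro` so both drugs share one scale.
  Observed delta endpoints are double-delta transformed,
  `Δ(T) = (TxT − Tx0) − (VehT − Veh0)`, with the vehicle reference the
  per-time arithmetic mean over all vehicle animals, pooled across studies,
  and linearly interpolated at non-tabulated times.  Urine endpoints are
  timestamped at the midpoint of their collection interval (1, 3, 5.5 h for
  the 0–2/2–4/4–7 h intervals).

**Numerics.**  Both ODEs are scalar and linear, so the production solver is
an exact exponential integrator on a fine uniform grid (0.1 h chronic,
0.01 h acute): the decay is handled analytically via the integrating factor
and the drive by trapezoidal quadrature, processed in blocks so the
exponential weights cannot overflow.  This is unconditionally stable, exact
for the homogeneous part, vectorizes across all animals at once (which the
pooled fit needs), and matches `scipy.integrate.solve_ivp` (LSODA,
rtol 1e-8) within 0.1% in the tests — the adaptive solver is kept as the
independent cross-check rather than the production path.

### Two-stage estimation

Stage 1 fits each dosed animal's PK by maximum likelihood under a
proportional residual error model, realized as least squares on
`(obs − pred)/obs` (weighting by the observed value keeps the objective a
genuine least-squares problem and avoids the degeneracy of
prediction-weighted residuals, where inflating predictions shrinks their own
weights).  Parameters are log-transformed; `Imax` is logit-transformed and
so bounded in [0, 1] (whether the source fit estimated or fixed Imax is
unstated; it is estimated here).  Where per-animal data cannot support the
full structure (two-compartment chronic PF, acute eplerenone), `Q` and `V2`
are fixed at population values — mirroring the parameter fixing used in the
unified acute-study model — and consistent with between-animal variability
being placed only on absorption, clearance and volume.  Fits with fewer
observations than free parameters fail explicitly; non-convergence is
flagged, never silent.

Stage 2 fixes the individual PK and fits each PD system to both drugs'
data pooled, sharing `Kin`/`Kin,max`, `Kout` (and `Imax`) across drugs with
one potency per drug.  Per-animal UACR baselines are not free parameters of
the outer optimization: the turnover ODE is linear, so the prediction is
affine in `uacr0` and the weighted-least-squares optimum for each animal's
baseline is computed in closed form inside the objective (profiling).  UACR
uses proportional residuals (strictly positive, right-skewed); delta
endpoints use additive residuals (they can be negative).  Vehicle
aldosterone animals enter the UACR fit with zero drive; sham (no
aldosterone) animals are excluded from fitting.  The outer optimizer is
`scipy.optimize.least_squares` (Levenberg–Marquardt) with 5 jittered
restarts by default for PD fits (the UACR objective couples Imax and the
potencies); stage-1 PK fits default to a single start from
population-typical values — the profiles are monotone in each parameter
around the optimum and no multimodality was observed, while multistart
multiplies stage-1 cost by the restart count.  Starting from typical values
also selects the conventional branch of the absorption/elimination
("flip-flop") ambiguity that exact oral data admit.

Confidence intervals: asymptotic (curvature-based, on the transformed
scale) by default; case-resampling bootstrap CIs (subjects resampled within
group, percentile intervals, fresh subject ids so duplicates count twice)
via `bootstrap_ci`.  The CI method behind the published potency table is not
stated; bootstrap is this package's choice.

### Therapeutic index

`fEC50 = EC50·fu`; normalized potency `fEC50 / IC50_invitro`;
`TI = normalized serum-K⁺ potency / normalized UACR potency`.  fu and in
vitro potency cancel within a drug, so TI equals the raw total-EC50 ratio;
the implementation asserts the identity and the table reports both chains.
Display values are rounded to 3 significant figures; internal arithmetic is
full precision.  The TI fold-ratio between drugs uses the table TI values
(84.0/1.47 → 57-fold); the abstract-style rounding (83.8) is a display
difference the package does not attempt to resolve.

## Synthetic study conditions

The generator's defaults are the study conditions.  Values printed in the
source record: group structure (chronic: sham-vehicle, aldosterone-vehicle
and three dose arms per drug, n = 11; eplerenone 15/50/450, PF-03882845
5/15/50 mg/kg BID at 6 am/4 pm → alternating 10/14-h intervals, 27 days),
sampling schedules (PK Days 1/14/26/27 with the terminal sample 16 h after
the final dose; UACR Days 0/14/25; serum K⁺ Days 0/14/27; acute doses
3/10/30 mg/kg PF and 5/30/300 mg/kg eplerenone, urine midpoints 1/3/5.5 h,
plasma 0/1/2/4/7 h), and the PD potency truths (UACR IC50 10.4/671 nM;
serum-K⁺ EC50 874/988 nM total; acute normalized EC50 3.10/5.92).

Everything else is an artifact choice, fixed once and documented here:

* PK typicals (chronic PF: ka 1.2/h, CL 1.6→3.2 L/h/kg, V1 3, Q 0.8, V2 3;
  chronic eplerenone: ka 0.8, CL 2.5→4.0, V1 4; acute PF: ka 1.5, CL 2.0,
  V1 4; acute eplerenone: θ₁ 3.0 at 30 mg/kg, pwr 0.25, V1 1.5, Q 1, V2 3;
  1-h zero-order input), chosen to give rat-like half-lives (~1 h) and
  exposures that bracket the potency truths across the dose range.
* UACR turnover: Kin 7.9/day, Kout 0.08/day, Imax 0.95, baseline
  uacr0 ~ lognormal(mean 30, CV 30%) — the untreated aldosterone group
  roughly triples its UACR by Day 26 (the qualitative pattern of the
  published group-mean figures).  Serum K⁺: Kin,max 0.22 mmol/L/day, Kout
  0.35/day, baseline 4.3 ± 0.25 mmol/L with an aldosterone-induced drift of
  −0.012 mmol/L/day (vehicle serum K⁺ falls under aldosterone; the drug
  restores it — the double-delta transform removes the shared drift).
  Acute Na⁺/K⁺: Kin,max 0.9/h, Kout 0.30/h, baseline 3.5 ± 0.5.
* Between-animal variability: lognormal, CV 25% on ka and CL, 20% on V
  (none on Q/V2).  Residual error: proportional CV 15% (concentrations),
  20% (UACR); additive SD 0.15 mmol/L (serum K⁺), 0.25 (Na⁺/K⁺ ratio).
* Acute group size n = 10.  The acute study's group size and noise are not
  in the printed record at all; they were calibrated once so that the
  single-study estimator's sampling spread matches the published 95%
  interval of the acute normalized EC50 (1.58–4.62) — i.e. the synthetic
  study reproduces the reported precision, not just the point estimate.

What the generator does **not** emulate: body-weight growth, LLOQ censoring
of trough samples, circadian structure in urine chemistry, dropout, or any
histology/gene-expression/osteopontin endpoint.  Passing recovery tests
therefore show that the estimation machinery is correct and well-calibrated
under the assumed statistical structure — not that the published in-vivo
group comparisons would reproduce from new animals.

## Problem sizes and reproducibility

The replicate recovery studies (tests and `scripts/acceptance.py`) use 20
simulated study pairs per setting with two jittered optimizer starts per PD
fit — the package's desk-scale choice for a batch that runs in minutes on
one CPU.  Every stochastic step (generation, restart jitter, bootstrap)
draws from `numpy.random.default_rng` seeded explicitly; identical seeds
give byte-identical datasets and reports.

## Known limitations

* Two-stage estimation approximates the original nonlinear mixed-effects
  fit: per-animal PK estimates stand in for empirical-Bayes estimates, and
  shrinkage is absent.  With 10 concentration points per animal this is
  adequate for potency recovery but understates PK uncertainty.
* Oral-only data admit the flip-flop ambiguity; fits are started from
  population-typical values, which selects the conventional branch.
* No saturable elimination, lag times, effect compartments, tolerance or
  enterohepatic recirculation; covariate modeling is limited to the
  dose-dependent clearance power model.
* UACR units are treated as opaque; baselines are study-internal.
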