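# Methods

## Structural models

Each hormone is described by one-compartment disposition (clearance CL [L/h],
central volume V [L], elimination rate constant k = CL/V) with two absorption
routes from the weekly patch. The dose basis is the labelled patch content
(2.3 mg EE, 2.6 mg LNG) multiplied by the fixed overall bioavailability F
(0.30 EE, 0.27 LNG); a delivered-amount basis (210 µg EE / 840 µg LNG per
wear week) can be configured instead by supplying the amounts and F = 1. The
route split F_rel assigns F_rel·F to the zero-order central route for EE and
to the first-order route for LNG; the complement goes to the other route.

Closed forms, superposed over all applications (no state reset between
patches):

* zero-order central infusion at rate R0 for duration D1 = 168 h:
  C(t) = (R0/CL)(1 − e^(−kt)) during the infusion, washing out
  monoexponentially afterwards;
* first-order depot (EE): the depot share enters as a bolus at application
  time and follows the Bateman equation; at |ka − k|/k < 1e−8 the analytic
  limit (A0·k·t/V)·e^(−kt) is used;
* depot infusion (LNG): a zero-order infusion at rate R0d for duration D2
  into the depot, obtained by convolving the Bateman kernel with the infusion
  window; expressed via the cumulative kernel Φ as R0d·(Φ(t) − Φ(t − D2)).

The EE depot input shape is a design choice: the model description only
states first-order absorption from a dosing compartment, and a bolus load at
application time is the minimal reading. For LNG the depot is loaded by the
estimated-duration zero-order infusion, as described.

Internal units are hours, litres and nanograms; 1 ng/L ≡ 1 pg/mL, so central
concentrations are reported in pg/mL without conversion. AUCs are reported in
h·ng/mL (pg·h/mL ÷ 1000).

An independent ODE oracle (`structural.ode_oracle`) integrates the
depot/central amount system segment-by-segment between dosing and
infusion-stop breakpoints (LSODA, rtol 1e−11) and is used in tests to verify
the closed forms; agreement is ~1e−10 relative on random parameter sweeps
spanning two decades per parameter.

## Week-3 occasion effect

The LNG model carries multiplicative week-3 effects on V and CL. They are
treated as an occasion covariate: the concentration reported at a time in
week w is the full superposition history evaluated with the week-w parameter
set (weeks 1–2 base; weeks ≥ 3 scaled). By default the effect **persists**
from week 3 through the end of the regimen — the conservative steady-state
assumption consistent with week-12 exposure matching week 3 — with a
`week3_only` mode available. The ODE oracle applies the same convention, so
analytic/ODE equivalence is exact rather than approximate. The alternative —
switching parameters mid-integration at t = 336 h — would carry the week-1/2
state across the change and make the closed form inapplicable; since the
effect was estimated on two-occasion data, neither convention is more
faithful, and the occasion reading keeps every profile an exact superposition.

## Population model and simulation

Interindividual variability is log-normal on CL, V, ka (EE) and CL, V, F_rel
(LNG); F_rel varies on the logit scale so individual values stay in [0, 1].
Omega is diagonal (no covariances are published). Draws use one master seed
with deterministic per-subject substreams, so subject i's parameters do not
depend on how many subjects are drawn.

The extended-regimen study simulates 1000 individuals per hormone over 12
weekly applications plus a patch-free week, on hourly grids (169 points per
requested wear week, windows [(w−1)·168, w·168] with inclusive endpoints).
IIV is on; residual variability is never added to simulated profiles, only to
generated trial observations.

### Default parameter values (derived)

The originally fitted estimates exist only as image supplements, so the
shipped YAML configs are **calibrated**: `calibrate.calibrate_theta` tunes
CL, V, ka, F_rel (plus D2 and the week-3 multipliers for LNG) by least
squares on the log scale so that the typical-subject simulation matches the
published weekly geometric means of Cmax, AUC(0–168) and Css(48–168) at weeks
1, 3 and 12. This relies on the approximation geometric-mean(metric) ≈
metric(typical parameters), exact for AUC (∝ 1/CL with log-normal CL) and
accurate to a few percent for the peak metrics — which is why the full
population simulation reproduces the published geometric means to ~1–3%
rather than exactly. Omegas are set once from the published week-1 geometric
CV% for clearance (ω = sqrt(ln(1 + cv²)) ≈ 0.30/0.31) and plausible phase-1
magnitudes for the rest (ω_V 0.25/0.20, ω_ka 0.30, ω_F_rel 0.5 logit-scale);
residual error defaults to 15% proportional. The calibrated values are not
presented as the original estimates.

## Synthetic trials

The trial generator emulates the source study's cycle-2 design: 18 subjects,
samples at 0, 6, 12, 24, 48, 72, 120, 144, 168 h after the first and third
weekly applications plus 174, 180, 192, 216, 240 h after the third, giving 23
records per subject after deduplicating the shared window joins. Pre-dose
samples at an application instant take the trough of the running
superposition (the new dose contributes nothing at its own start). Assay
LLOQs are 2 pg/mL (EE) and 50 pg/mL (LNG); values below are censored with a
BLQ flag. Residual error defaults to proportional in exponential form,
dv = f·exp(σε): observations stay positive, the implied CV sqrt(e^(σ²) − 1)
≈ σ for small σ, and the likelihood is exactly Gaussian on the log scale.
Additive and combined forms are available for generation.

What the generator does **not** emulate: cycle-1 carry-over into the cycle-2
pre-dose sample (the synthetic cycle starts drug-free, so the t = 0 sample is
always BLQ), physiological between-cycle drift (e.g. binding-globulin
dynamics), dropout, adherence lapses, and assay-batch effects. Passing
recovery tests therefore show the estimators work when the model family is
correct, not that the model family is correct for real data.

## Estimation

`fit_two_stage` fits each subject by unweighted least squares on log
concentrations (the exact likelihood under the exponential-proportional
error), then takes transformed-scale means and SDs across subjects for the
typical values and omegas. It requires ≥ 6 quantified observations per
subject and is the default initializer.

`fit_laplace` maximizes the Laplace-approximated marginal likelihood. The
inner problem (per-subject random-effect modes) is solved by a damped
Gauss–Newton iteration vectorized across subjects, with forward-difference
Jacobians (step 1e−5) and per-subject backtracking; the inner curvature uses
the Gauss–Newton approximation (the FOCE-style Hessian), which keeps the
objective smooth and cheap. The inner solve is cold-started from η = 0 on
every outer evaluation so the objective is a deterministic function of the
outer parameters — warm starts made finite-difference outer gradients
unreliable. The outer optimizer is L-BFGS-B on log/logit-transformed
parameters (FD step 1e−5, relative objective tolerance 1e−10). RSEs come from
a central-difference observed-information matrix; on the log scale SE(log) is
reported directly as relative SE. F (with F_rel, jointly non-identifiable)
and D1 = 168 h are always fixed; requesting a free F raises an
identifiability error. D2 is fixed at its initial value unless explicitly
freed. BLQ records are dropped by default (LLOQ/2 substitution available);
all-BLQ subjects are excluded with a logged warning.

Diagnostics: `gof_diagnostics` returns population/individual predictions and
log-scale weighted residuals (standard normal under a correct
proportional-error fit); `vpc` simulates ≥ 200 replicate trials at the
observed design and brackets each observed percentile with the central 90%
interval of its simulated counterpart.

## NCA conventions

* Linear trapezoid on rising/flat intervals and wherever a concentration is
  ≤ 0; log trapezoid (C1 − C2)·Δt/ln(C1/C2) on strictly falling positive
  intervals — exact on monoexponential decay segments of any grid spacing.
* Window bounds must be grid points (hourly grids make this automatic);
  Tmax is the grid argmax, ties to the earliest time, reported as elapsed
  time within the window; Tmax is never summarized (reported "NC"), matching
  the published tables.
* Css(0–168) = AUC/168; Css(48–168) uses divisor 120 (the published tables
  list the column without its formula; AUC/window-length is the assumption).
* Accumulation ratios are computed per subject against the same subject's
  reference week and then summarized; for geometric means this equals the
  ratio of weekly geometric means exactly, an identity the tests exploit.
* Summary tables report arithmetic mean/SD/CV% and geometric mean/geometric
  CV% (100·sqrt(e^(s²) − 1), s = SD of natural logs), displayed at 3
  significant figures with full precision retained in machine-readable
  output.

## Problem sizes and numerical choices

The replicate recovery study uses 20 synthetic trials of 50 subjects with a
dense 35-sample schedule (ten samples in each of three wear weeks plus
washout samples out to 336 h after the last application — the washout tail is
what identifies slow first-order absorption) at 15% proportional error; the
EE model's typical values come back with median relative bias under 10% and
omegas within ±50%. The LNG route split (F_rel, ka, D2 jointly) is weakly
identified at 18 subjects — the same pressure that forced F to be fixed — so
the LNG checks assert clearance and week-3 effect recovery only. The
acceptance script simulates 1000 individuals per hormone and cross-checks
the closed forms against the ODE oracle on 25 random draws per drug.

## Known limitations

* Single-compartment disposition; no binding-globulin dynamics, no
  enterohepatic recirculation, no dermal-depot physiology beyond the two
  input routes.
* No covariates (the source analysis performed none); omega is diagonal.
* The calibrated defaults inherit the identifiability of the calibration
  targets: several (F_rel, ka, D2) combinations fit the nine weekly
  geometric means nearly equally well, so individual default values should
  not be over-interpreted even though the simulated summaries are stable.
* Estimation supports the proportional (exponential) residual model only;
  the generator's additive/combined options are for data generation.
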