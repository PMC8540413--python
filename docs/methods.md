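# Methods

## The model

Levetiracetam given as an intravenous zero-order infusion is described by a
two-compartment linear disposition model with parameters CL (total
clearance, L/h), V1 (central volume, L), Q (intercompartmental clearance,
L/h) and V2 (peripheral volume, L). Concentrations refer to the central
compartment (plasma). In macro form the single-dose solution is a sum of two
exponentials with rate constants `alpha >= beta > 0`, the roots of
`s^2 - (k10+k12+k21) s + k10*k21`, where `k10 = CL/V1`, `k12 = Q/V1`,
`k21 = Q/V2`; the central bolus coefficients `A = (alpha-k21)/(alpha-beta)`
and `B = (k21-beta)/(alpha-beta)` satisfy `A + B = 1`. During an infusion of
duration `T` at rate `R0 = dose/T` the within-infusion branch
`(R0/V1) * sum_i (C_i/lambda_i) (1 - e^{-lambda_i t})` applies; after the
infusion each term decays as `e^{-lambda_i (t-T)}`. Steady state under a
repeating interval `tau` multiplies each exponential term by its
accumulation factor `1/(1 - e^{-lambda_i tau})`; the solution is
tau-periodic, so the pre-dose value equals the trough at `t = tau`.

Population clearance depends on urinary creatinine clearance (CrCl, mL/min)
through an additive power law centred at 120 mL/min:

    CL (L/h) = theta_nr + (CrCl / 120)^theta_r

with `theta_nr = 3.5` L/h and `theta_r = 2.5` in the final model. The form
is deliberately additive (not the more common multiplicative power):
`theta_nr` acts as a non-renal clearance floor, and the equation yields
4.5 L/h at CrCl 120 and 9.2 L/h at CrCl 240. Between-subject variability is
exponential (log-normal) on CL and V1 — `CL_i = CL_typ(CrCl_i) e^{eta_1}`,
`V1_i = 20.7 e^{eta_2}` L — with independent normal etas of SD
`omega_CL = 0.327` and `omega_V1 = 0.561` (reported as 32.7% and 56.1%; we
read the table percentages as `100*omega`, the dominant reporting
convention — the CV reading `sqrt(exp(omega^2)-1)` differs by under 3% at
these magnitudes and is switchable by passing different `OmegaSpec` values).
Q (31.9 L/h) and V2 (33.5 L) carry no random effects, and no eta
correlation is modelled. Residual variability is proportional,
`y = f (1 + eps)`, `eps ~ N(0, 0.223^2)`; additive and combined models are
available.

## Estimation (FOCE with interaction)

The marginal likelihood is approximated subject by subject. Each subject's
conditional mode `eta_hat` minimises

    l(eta) = sum_j [ (y_j - f_j(eta))^2 / v_j(eta) + log v_j(eta) ]
             + eta' Omega^{-1} eta,

with the residual variance `v` evaluated at the conditional prediction (the
"interaction"). Linearising `f` around `eta_hat` with Jacobian
`G = df/deta` gives the subject contribution

    OFV_i = log det V_i + r_i' V_i^{-1} r_i,
    V_i = G Omega G' + diag(v),  r_i = y - f(eta_hat) + G eta_hat,

and the objective function value (OFV) is the sum over subjects, on the
NONMEM convention (`-2 log L` without the `n log 2pi` constant) so that
differences between nested models are chi-square distributed.

Numerics. The inner search is a Levenberg-damped Newton per subject: the
gradient of `l` is exact given `G` (the variance is an explicit function of
the prediction), the Hessian uses `G' diag(d2l/df2) G + 2 Omega^{-1}`
(exact up to the `d2f/deta2` term), steps are capped at norm 3 with
`|eta| <= 8`, and damping adapts per subject up to `lambda ~ 1e12` within a
round. The hot path is compiled with numba; a pure-numpy engine with the
same algorithm backs the generic API (`foce_objective`) accepting arbitrary
prediction functions, and the two agree to ~1e-6 OFV units on a 200-subject
dataset. `V^{-1}` and `log det V` use the Woodbury identity with the
diagonal Omega. Fixed effects and variance parameters are optimised on log
scale by L-BFGS-B inside physiological boxes (e.g. volumes and clearances
in [0.05, 500], omegas in [1e-3, 4]); the boxes keep every trial point's
OFV finite so line searches stay informative. If the quasi-Newton run fails
to improve on the initial OFV (its finite-difference gradients sit at the
inner solver's noise floor, ~1e-6 OFV units), a Nelder-Mead polish is run
from the same point. Convergence uses scipy's `ftol` on the OFV (default
1e-9 relative); standard errors come from the central-difference Hessian of
the OFV with relative steps 1e-4, covariance `2 H^{-1}`. Eta shrinkage is
`100 (1 - SD(EBE)/omega)` (SD with one delta degree of freedom), epsilon
shrinkage `100 (1 - SD(IWRES))`.

Stepwise covariate modelling adds, one at a time, the candidate with the
largest OFV drop of at least 3.84 (5% chi-square, 1 df), then removes any
included covariate whose deletion raises the OFV by at most 6.63 (1%).
Ties at the forward step break toward the larger drop, then lexically. The
nonparametric bootstrap resamples subjects with replacement to the original
subject count and re-fits each replicate from the original estimates
(`maxiter` 60, `ftol` 1e-8 — percentile summaries do not need tighter
convergence); failed replicates are counted and excluded, and more than 50%
failures abort with a diagnostic error.

## Synthetic cohort

The generator emulates the clinical design: 27 ICU subjects at steady state
on 500/1000/1500 mg q12h (18/6/3 subjects) as 30-min infusions, samples at
0 h (pre-dose), 0.5 h, one draw in each of 1-2, 3-5 and 6-8 h, and 12 h;
four subjects lose one random mid-interval sample (27*6 - 4 = 158 samples),
and concentrations below the 2 mg/L assay limit are censored (dropped by
default, configurable to LLOQ/2 or zero). CrCl is drawn from a log-normal
with median 117 mL/min truncated to the observed [54, 239] range, with
log-SD 0.3176 chosen so that P(CrCl > 130), the augmented-renal-clearance
fraction, is 37% as in the cohort; a single truncated log-normal meets both
anchors, so no mixture is needed. Other covariates use truncated normals
(log-normals for right-skewed labs) spanning the cohort's median and range;
diagnosis is multinomial 10/8/9 over stroke/trauma/other and sex is
Bernoulli 18/27 male. Covariates are drawn independently of each other and
of dose allocation — the cohort's joint structure is unreported — so
analyses that depend on covariate correlations (e.g. confounded selection)
are not exercised by these data. Steady state is encoded by a flagged dose
row with the interval (closed form), which a tested property shows is
equivalent to enumerating 50 historical doses to within 0.1%.

All randomness flows from one seed through purpose-named child streams
(covariates, design, eta, residual), so toggling residual noise never
changes the eta sequence, and equal seeds give bit-identical datasets.

## Dosing simulations (PTA)

For each CrCl group (80-240 mL/min by 40, all subjects exactly at the group
value) 1000 parameter sets are drawn and each regimen on the grid (500-2000
mg, q12h or q8h, 30-min or 2-h infusion) is evaluated by the closed-form
steady-state trough; the probability of target attainment is the percentage
of subjects whose trough exceeds 6, 12 or 46 mg/L. Within a group all
regimens share the same draws (common random numbers), making
dose-monotonicity exact per draw. Residual error is excluded from the
trough by default — the target refers to the subject's true concentration —
with a flag to include it; a 4e5-draw comparison of the two readings
against the published table cells favoured exclusion uniformly. Monte Carlo
SE at n=1000 is at most 1.6 percentage points.

## Diagnostics

CWRES are the FOCE-linearised residuals `V^{-1/2} (y - f(eta_hat) + G
eta_hat)` using the symmetric inverse square root per subject; under a
correct model they are approximately standard normal. The pcVPC bins
observations by the nominal design times (pre-dose, end of infusion, the
three windows, trough; bins under 5 observations merge leftward), corrects
each observed and simulated value by (bin median population prediction) /
(own population prediction), and compares the observed 10th/50th/90th
percentiles with the 95% band of the same percentiles across simulated
replicates of the original design (1000 by default).

## Noncompartmental analysis

AUC over the dosing interval uses the linear-log trapezoidal rule: the
logarithmic trapezoid on declining segments with positive endpoints, the
linear trapezoid on rising, constant or zero-bounded segments. The terminal
slope is the best-adjusted-R^2 log-linear regression over the last 3, 4, ...
points excluding the observed peak (the convention of standard NCA
software; the source names only the software). Steady-state clearance is
`dose/AUC_tau` (no extrapolation), `t1/2 = ln 2 / lambda_z`,
`Vz = CL/lambda_z`.

## Verification scale and expectations

The test suite runs everything at sizes chosen for a few minutes of
runtime: the structural solution is checked against an independent ODE
integration on 100 random parameter sets; parameter recovery uses one
200-subject study (theta_nr within 10%, theta_r within 20%, V1 within 15%,
omega_CL within 25%, sigma within 15%); the bootstrap runs 200 replicates
(scaled down from the reported 2000) on one 27-subject study. Selection
calibration runs 50 replicates: the type-I rate of the forward gate is
checked at the 27-subject design, while the power check uses a 100-subject
cohort — at n=27 the gate's power for the true CrCl effect is only ~65%
(typical OFV drops of 2-16 units), an information limit of the small
cohort rather than a property of the selection machinery. Likewise the
bootstrap CI covering the generating theta_nr is a ~90% property over
27-subject study realisations, not a certainty for any one of them.

Because the patient-level data are not public, nothing here reproduces the
cohort's own estimates; passing tests show that the pipeline recovers known
truths from data generated under its own assumptions (correct likelihood,
calibrated selection, honest uncertainty), plus the published quantities
that are functions of the final model (clearance anchors, dosing tables).
Real ICU data add model misspecification, time-varying renal function,
occasion effects and correlated covariates, none of which the generator
emulates.

## Known limitations

- One eta correlation structure (diagonal) in estimation; sampling supports
  correlated etas.
- No inter-occasion variability, oral absorption, or nonlinear elimination.
- BLOQ handling is row-level (drop/LLOQ-half/zero); no likelihood-based
  censoring (M3).
- The repeated-root (alpha == beta) two-compartment degeneracy raises an
  error rather than switching to the analytic limit; it is a measure-zero
  parameter set not reachable from data-driven fits.
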