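# Methods

## Model structure

The baseline system couples nine cell populations and five cytokines through
mass-action terms: every activation/production process `A + B -> C`
contributes `λ A B` to C's equation and every inhibition `D ⊣ E` contributes
`−δ D E`.  T-cell activation rates are multiplied by the naive T-cell
density (a stabilizing bookkeeping device: every helper/cytotoxic/regulatory
activation flux is simultaneously subtracted from the naive pool).
Macrophage activation saturates through a `(M₀ − M)` factor and cancer
growth through the logistic factor `(1 − C/C₀)`.  Necrosis production is
`α_NC ×` the cancer death flux; the death bracket is computed once and
shared between the cancer and necrosis equations, so the coupling is exact
by construction, not by duplicated code.

The treatment extension keeps every printed sign, including the minus sign
on the macrophage-shielding term `δ_5fuM [5FU][M]` inside the cancer death
bracket and inside the 5-FU consumption bracket.  The bracket can therefore
in principle go negative at extreme macrophage excess; states are never
clamped, and the integrator emits a warning when the net bracket is negative
on more than 1% of grid points.  Leucovorin has no cytotoxic term of its
own: every leucovorin action multiplies the 5-FU concentration, so with zero
5-FU dose the cell dynamics are provably independent of the leucovorin dose
(a property the tests verify both symbolically, at the RHS level, and
numerically).

State ordering is frozen as (T_N, T_h, T_C, T_r, D_N, D, M, C, N, H, μ₁,
μ₂, Iγ, Gβ) + (5FU, LV, Ir).

## Dimensionless working scale

Each cell/cytokine variable is scaled by its untreated steady-state value,
making the untreated fixed point the all-ones vector; each drug D is scaled
as `D̄ = δ_D [D] / A_daily_median`, where δ_D is its natural decay rate and
the daily-median rate is the cohort median dose per cycle divided by the
14-day cycle length (the only reading in which the units close).  Under a
hypothetical continuous infusion at exactly the daily-median rate with no
consumption, D̄ equilibrates at 1.  A single cohort-level scale is used for
all patients so trajectories are comparable across regimens.

## Parameter derivation

The 59 baseline parameters are not taken from fitted values; they are
derived from steady-state flux balance at the all-ones state:

- Each variable has a configured total turnover rate (per day).  Removal
  weights allocate the turnover among that variable's removal terms; each
  rate is weight × turnover divided by the term's state factor at
  equilibrium (1 for most, `M₀ − 1` for macrophage activation, `1 − 1/C₀`
  for the logistic factor; a zero factor with positive weight is an error).
- Production is set equal to removal and allocated by production weights.
- The naive-cell sources A_TN and A_DN absorb the residual: the T-cell
  activation rates are fixed by the helper/cytotoxic/regulatory balances,
  and the shared dendritic rates δ_DH, δ_D by the activated-DC balance, so
  the naive equations have no free turnover of their own beyond δ_TN.
- α_NC = δ_N / (cancer death flux at equilibrium) = turnover_N / turnover_C.

Default turnover rates are engineering choices on biological timescales:
cells 0.05–0.2 /day (macrophages slowest), cancer 0.02 /day, necrotic
clearance 0.01 /day (α_NC = 0.5), cytokines 3–4 /day (half-lives of a few
hours).  Allocation weights default to equal shares.  M₀ = C₀ = 2 place the
equilibria at the midpoint of their saturation factors.  All of these are
config-overridable (YAML); the derivation is a pure function of the config.
With the defaults the all-ones equilibrium is linearly stable (largest
Jacobian eigenvalue ≈ −0.01 /day), so the untreated system holds its steady
state over decade-long simulations, treated tumors regrow after the course
ends, and small-tumor initial conditions converge to steady state — the
qualitative regime the simulation experiments probe.  Absolute timescales
are not identifiable from composition data, so no claim is made that the
defaults reproduce any particular fitted trajectory.

### Treatment parameters

Kill rates use survival-fraction calibration: "e efficient per cycle" means
the drug acting alone removes the fraction e of its target per cycle under
the median regimen, giving `δ = −ln(1 − e)/E` with E the integral of the
dimensionless concentration over one cycle (closed form: E = cycle length at
the median dose; the leucovorin/5-FU synergy uses the joint exposure
`∫ [5FU][LV] dt ≈ 90.8`, computed by quadrature of the analytic decay-only
profiles).  Defaults: irinotecan 40% efficient against cancer, 5-FU 25%,
incremental leucovorin effect 15% (both below irinotecan, which is the
distinctly strongest agent), irinotecan T-reg depletion 30%.

Synergy/auxiliary rates are fractions of their parents: δ_C5fuIγ = 0.10 and
δ_5fuM = 0.25 of δ_C5fu (macrophage-mediated chemoresistance is the
dominant immune modifier of 5-FU), λ_*D5fu = 0.20 of the corresponding
baseline activation rates, δ_5fuD = 0.05 of δ_5fu.  Consumption constants
α_* make each interaction's drug loss 5% of natural decay at the reference
(all-ones, unit-drug) state — tumor uptake is small against systemic
clearance.  Natural decay comes from plasma half-lives: 5-FU 0.35 h
(≈ 47.5 /day; ~80% of elimination is hepatic, recorded as a config anchor),
leucovorin 6 h, irinotecan 12 h.

## Numerical integration

The infusion forcing is piecewise constant with half-open windows
(irinotecan [0, 1 h), leucovorin [1 h, 2 h), 5-FU [2 h, 48 h) within each
cycle).  The integrator restarts at every breakpoint and holds the injection
rates constant inside each segment, so the solver never steps across a
discontinuity; LSODA (stiff-capable) with rtol 1e-8 / atol 1e-10 integrates
each smooth piece, with per-segment dense output for evaluation at arbitrary
days.  States are not clipped: any component below −10 × atol fails the run.
Halving the tolerances changes end-of-course cancer by < 1e-4 relative.

## Sensitivity analysis

Forward sensitivities are integrated one parameter at a time as an augmented
17 + 17 system, with the Jacobian ∂F/∂X and the parameter derivative ∂F/∂θ
both computed by central finite differences with step `1e-6·max(1, |·|)`
(one differentiation rule, one oracle test).  S(0) = 0 — parameters do not
affect initial conditions.  Relative sensitivities S̄ = S·θ/X are masked
(NaN, with a warning) where |X| < 1e-8, since cancer approaches zero after
strong treatment; time averages use trapezoidal quadrature over [0, T] with
T defaulting to the treatment course plus two years.  Ranking uses the
magnitude of the absolute time-averaged sensitivity as the primary order
(the relative variant is reported alongside): the absolute variant measures
how much the output moves per unit rate change and is the quantity in which
the leucovorin/5-FU synergy dominates, because its calibrated rate is an
order of magnitude smaller than the direct kill rates at a comparable
per-course effect.  "Immune-interaction treatment parameters" are the five
drug-to-immune-cell couplings {δ_5fuM, δ_TrIr, λ_ThD5fu, λ_TCD5fu, δ_5fuD};
the IFN-γ synergy δ_C5fuIγ is classified as a drug–cytokine term.

Verifying sensitivities against central finite differences of two full
simulations requires the oracle simulations to be substantially tighter
(rtol 1e-12) than the perturbation times the sensitivity, otherwise solver
noise divided by 2εθ dominates the comparison; the tests use sup-norm-scaled
per-variable errors for the same reason.

## Synthetic cohorts

The generator emulates the statistical shape of deconvolution-derived
records, not their biology: immune fractions of 22 cell types are Dirichlet
(concentration 200) around five synthetic centroids whose only anchored
feature is the ordering of the T-reg/T-helper ratio (cluster 3 highest,
cluster 2 lowest); tumor dimensions are log-normal (medians 5.0 and 3.2 cm,
σ = 0.35); necrosis is Beta with mean 0.1; per-cycle doses are uniform
between the cohort minimum and twice the median; cycles default to 12 × 14
days.  Follow-up days are uniform over treatment start + [150, 1200] days so
that cohorts straddle the recurrence boundary and contain both tumor-free
and with-tumor observations.  Generation is a pure function of
(n, cluster mix, seed, config).

What passing tests on these cohorts show is internal consistency of the
pipeline (self-consistent labels give AUC 1; pure label noise gives chance
AUC), not predictive performance on real patients: real records carry
co-administered drugs, surgery between follow-ups, deconvolution error and
dosing heterogeneity that the generator deliberately omits.

## Validation conventions

Tumor-free is the positive class; a record is classified tumor-free when its
predicted cancer value is below the threshold.  Thresholds sweep a uniform
grid (default 101 points) spanning the prediction range, with the standard
(0,0)/(1,1) anchors completing the curve so a perfectly separating predictor
integrates to AUC exactly 1.  "Large" tumors are those whose initial
dimensionless cancer density is ≥ 0.5 (half of steady state), matching the
half-of-initial matching rule; the cutoff is config-overridable.  The T-reg
pre/post comparison groups patients by pre-treatment T-reg (median split by
default) and applies a paired t-test (Wilcoxon available by config); a
zero-variance difference reports p = 1.

## Known limitations

- No pharmacokinetic compartments, no spatial or stochastic variants.
- Parameter values are steady-state reconstructions under configurable
  assumptions, not fits to longitudinal data; only structure, signs and the
  calibration anchors (40% irinotecan efficiency, 80% hepatic 5-FU
  elimination, Table-scale doses) are data-anchored.
- The per-patient simulations in cohort validation reuse cohort-level drug
  scaling and cluster-level initial conditions; per-patient dimensional
  anchoring (tumor-size-derived cell densities) enters only through the
  tumor-scalar utilities.
- The mapping from 22 deconvolved immune fractions to the model's aggregated
  cell classes is configuration, not data; fractions are carried on records
  for realism but do not feed the dynamics.
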