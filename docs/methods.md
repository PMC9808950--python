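# Methods

## Value function

The package values a health episode (EQ-5D-5L state Q, lifespan T in years)
as `V = (1 − β′X) · T^α`. The 20-element dummy vector X uses *incremental*
coding: a dimension at level L activates its first L−1 transition dummies, so
each β_k is the extra QALY loss of one severity step and β′X is the
cumulative decrement from full health. Transition decrements are hypothesised
positive but never constrained; a negative estimated level-1→2 coefficient is
reported as estimated, which is why a class's value-set maximum can exceed 1.
The power α bends value in lifespan: α = 1 is constant proportionality,
α < 1 decreasing marginal value of life-years. Anchors are structural:
full health for one year gives V = 1 (β′X = 0, 1^α = 1) and immediate death
gives V = 0 (0^α = 0 for any α > 0).

Value-set tabulations fix T = 1 so the lifespan factor drops out; lifespan
enters estimation only through the choice tasks. `value_range` reports the
min/max over the 3124 states *excluding* 11111, because full health is the
anchor rather than an estimate; the documented consequence is that the
maximum reflects the mildest estimated health deviation. When a class has
several negative level-1→2 coefficients, the maximising state combines all
of them; published tables that report the single best one-dimension
deviation will sit slightly below this tabulated maximum.

## Choice models

Choices are paired; with extreme-value errors the probability of choosing A
is `sigmoid(μ(V_A − V_B))`. Since V is on the QALY scale, the scale μ is a
free parameter — the conversion factor from QALYs to log odds — estimated,
not fixed at 1. The conditional logit (CL) uses one constant μ; the
heteroskedastic logit (HCL) models `μ_it = exp(γ′z3_it)` over a task design
z3 containing an intercept, a matched-pair indicator, and task-type-specific
response-duration bins {1–14, 15–29, 30–59, ≥60 s} (half-open), with the
15–29 s bin the latent-pair reference and the 30–59 s bin the matched-pair
reference. The A-vs-B and B-vs-C matched pairs share one indicator by
default (`merge_matched=False` splits them). Latent scale pairs have no
lifespan attribute; the package adopts the convention T_A = T_B = 1 so the
lifespan factor cancels, and any common-lifespan framing effect is absorbed
by the task-type scale dummy.

Both fits maximise the exact log-likelihood by L-BFGS with analytic
gradients; α is optimised as log α to keep it positive (the α < 1 hypothesis
is inspected afterwards, never imposed). Standard errors come from the
inverse observed information, with the Hessian obtained by central finite
differences of the analytic gradient and a delta-method transform for α.
Matched pairs within a block are treated as conditionally independent binary
tasks, matching the product-over-tasks likelihood.

## SALC mixture and EM

The scale-adjusted latent class model crosses M taste classes (β_m, α_m)
with S scale classes (γ_s). Membership is multinomial-logit on two distinct
covariate sets — z1 (demographics, EQ-VAS, own health, caregiving, cTTO
completion) for taste, z2 (demographics, stated difficulty items, cTTO
completion, survey length) for scale — with class 1 the reference in each,
so exponentiated coefficients are odds ratios versus class 1. Respondent i's
likelihood sums p(m|δ) p(s|θ) times the product of heteroskedastic-logit
task probabilities over the M×S grid.

Estimation is a generalized EM:

- **E-step**: posterior weights w_i(m, s) over the class grid, computed with
  log-sum-exp throughout.
- **M-step (membership)**: weighted multinomial-logit maximisation of δ
  against the posterior taste marginals and θ against the scale marginals.
- **M-step (structural)**: one capped L-BFGS run (default 40 iterations) on
  the posterior-weighted log-likelihood over *all* of {β_m, α_m, γ_s}
  jointly — the update cannot be split by class because every γ_s multiplies
  every taste class's value difference. Any ascent is accepted; an ascent
  guard keeps the previous parameters if the optimiser fails to improve, so
  the observed-data log-likelihood is provably non-decreasing. A decrease
  beyond numerical tolerance (1e−6 relative) raises `EMError`; the trace is
  stored on every `FitResult` and asserted in the test suite.

Identification relies on the model's built-in QALY anchor: the fixed "1" in
1 − β′X pins the value scale, so each γ_s intercept is that scale class's
QALY-to-log-odds conversion, and no further normalisation is imposed. The
known fragility of separating taste from scale empirically is mitigated by
the distinct z1/z2 covariate sets, multiple starts, and BIC screening.

Multi-start policy: starts are random perturbations around the pooled
(single-class) fit, with powers and scale intercepts spread across classes
and small random membership coefficients; start seeds derive from one user
seed. All starts run a short burn-in (default 12 EM iterations), the best
few (default 3) are polished to convergence (relative log-likelihood change
below 1e−8, at most 500 iterations), and every start's log-likelihood is
recorded. With `M = S = 1` the first start is the pooled fit itself, so
SALC(1,1) reproduces the HCL solution.

Model choice uses `BIC = −2ℓ + k·ln(N)` with N = respondents — the
respondent is the independent sampling unit of the mixture; using tasks
instead would over-penalise. Class labels are made canonical by sorting
taste classes by α ascending (the quality-of-life-oriented class first) and
scale classes by scale intercept ascending, re-referencing the membership
logits to the new first classes; the likelihood is invariant to this
relabelling. Fits with any prior class share below 0.5 % are flagged as
degenerate rather than silently reported. Mixture standard errors use
Fisher's identity (the observed-data score equals the posterior-weighted
complete-data score) with a finite-difference Hessian.

## Synthetic data generator

The generator emulates the ordinal arm of an EQ-VT valuation study: per
respondent, 10 latent scale pairs (states only) and 12 matched-pair blocks,
each a linked A-vs-B then B-vs-C comparison sharing the B episode — 34 tasks
in total. Half the respondents (configurable) receive a shared lifespan in
each block's first matched pair; 30 % are flagged as having completed cTTO
tasks beforehand. Defaults — 1000 respondents, the 10/12/12 task split, the
0.5 and 0.3 arm fractions — mirror the study conditions the package targets.
The lifespan menu {1, 2, 4, 7, 10, 15} years, the severity-stratified random
state pool, and the log-normal duration distributions are realistic
placeholders, not the study's confidential blocked design; an explicit
design CSV can be substituted since the estimators read the same long
format.

Pairs are drawn with a dominance filter: no emitted pair is weakly ordered
on all six attributes (five severity levels plus lifespan, ties included);
violating blocks are redrawn whole, since redrawing one side cannot fix a
pair whose other side is 11111 or 55555. Response durations are log-normal
with scale-class-specific parameters (defaults populate all four duration
bins), so duration carries genuine information about the latent scale class.
Choices are sampled directly from the logistic choice probability, which is
distributionally identical to adding independent Gumbel noise to both
utilities. Respondent covariates are independent draws from fixed
categorical distributions (overridable); correlation between difficulty
items and the realised scale class arises only through the membership
logits θ.

What passing tests on these data do and do not show: they demonstrate that
the estimators recover the parameters of their own data-generating process
at survey scale — correctness of the likelihood, EM, and selection
machinery — not that real respondents satisfy the model (no protocol
violations, interviewer effects, preference dynamics over the session, or
non-logistic noise are simulated).

## Numerical choices and problem sizes

- Optimiser tolerances: L-BFGS `ftol` 1e−12 / `gtol` 1e−8 for pooled fits;
  EM stops at 1e−8 relative log-likelihood change.
- T = 0 episodes contribute exactly 0 value; the α-gradient term
  T^α·ln T is set to its limit 0 there.
- Probabilities use `log_expit`/`logsumexp`; a degenerate −∞ log-likelihood
  warns rather than raises.
- Finite-difference Hessians use central differences with relative step
  1e−5 on the analytic gradient, symmetrised; singular information matrices
  fall back to the pseudo-inverse.
- Exact α ties in class ordering break by total decrement Σβ descending.
- The recovery study in the test suite uses n = 1000 respondents × 34 tasks
  with a two-taste truth (α = 0.1 vs 0.5) and 10 EM starts; the
  model-selection study uses 20 replicates at n = 500 with 2 starts per
  candidate — sizes chosen as the smallest at which the checks are sharp.

## Known limitations

- The value model is main-effects only: no cross-attribute interactions,
  no 3L crosswalks, no population-norm tabulations.
- Only the logit kernel is implemented (no probit, nested, or
  Zermelo–Bradley–Terry specifications; no continuous random-parameter
  mixing).
- Grade-of-membership covariate codings for the scale side are a
  reconstruction from survey practice and are deliberately configurable
  rather than fixed.
- cTTO responses themselves are neither simulated nor modelled; cTTO
  completion enters only as a membership covariate.
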