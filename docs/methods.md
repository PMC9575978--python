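# Methods

`incentdce` implements the full analysis workflow of a two-stage discrete
choice experiment (DCE) on financial-incentive smoking-cessation programs:
constructing the paired choice design, simulating respondent cohorts under a
random utility model, cleaning aberrant respondents, estimating a panel mixed
logit by maximum simulated likelihood (MSL), and deriving willingness-to-accept
(WTA) and predicted-uptake quantities. This note records the model, the
defaults and their units, the numerical choices, and what the synthetic data
do and do not demonstrate.

## The choice model

Respondent *i* facing task *t* sees two hypothetical programs (A, B) described
by five attributes — total incentive amount (£50–£1,000 over the 10-week
program), incentive type (cash/voucher), reward schedule
(consistent/escalating with reset), session frequency (fortnightly to three
per week), and location (healthcare center/workplace) — and may also decline
to enroll (opt-out). Utility is linear:

    V_ijt = α_g · (amount_jt / u) + Σ_k β_ik x_jtk            (programs)
    V_i0t = δ_g                                               (opt-out)

with i.i.d. type-I extreme-value errors, so choice probabilities are softmax.
Here:

- `u` is the amount rescale unit, **£10 per coded unit** by default. The unit
  is a pure reparameterization of `α`; WTA and uptake are invariant to it
  (tested).
- `x_jtk` are **effects-coded** categorical attributes: an L-level attribute
  yields L−1 columns; the omitted level is −1 in each, so level effects sum
  to zero within an attribute and the omitted level's effect is the negative
  sum of the estimated ones.
- `β_ik ~ N(b_k, w_k²)` independently across k (diagonal mixing): normal
  random coefficients shared across all of a respondent's tasks (panel
  structure). Only per-attribute SDs are identified/reported; correlations
  are out of scope.
- `α_g = α + γ_g` and `δ_g = δ + λ_g` carry fixed income-group interactions
  for middle/high income; low income is the reference.
- The opt-out row carries only the alternative-specific constant (ASC) and
  its income interactions; its attribute columns are zero. Under effects
  coding this makes program utilities relative to the attribute mean, which
  is what gives the ASC its "amount needed to make the average program
  worth joining" interpretation.

The two-stage survey response (pick a preferred program, then say whether you
would enroll) is mapped to a **single three-alternative choice**: the chosen
alternative is the opt-out when enroll = no, otherwise the preferred program.

## Design construction

The design search minimizes the null-prior (utility-neutral) D-error of the
paired conditional logit. For paired sets the information matrix at zero
coefficients is M = (1/4) Σ_s z_s z_sᵀ with z_s the coded difference between
the two alternatives, and the D-error is det(M⁻¹)^(1/p) for p coded columns
(+∞ when singular).

- **Search**: coordinate exchange over set × position × attribute × level,
  greedy accept, multi-restart from random starts (default 20 restarts in the
  CLI, 8 in the pipeline defaults). Candidate pairs that are identical, or
  strictly dominated when every attribute declares a preference direction,
  are rejected.
- **Amount coding in the search**: by default the money attribute is
  effects-coded over its seven levels inside the search objective
  (`amount_coding="factor"`), the fractional-factorial treatment. A linear
  money column is also available (and is the default metric reported by
  `d_error_null`), but optimizing it concentrates every set on the £50/£1,000
  extremes — which destroys amount-level balance and, downstream, starves the
  opt-out alternative of realistic choice pressure (almost nobody refuses a
  £1,000 program, so the ASC income interactions become separated). The
  factor treatment yields near-perfect balance across all seven amounts and
  beats random designs under both metrics.
- **Blocking**: 30 sets into 3 blocks of 10 by greedy assignment minimizing
  squared per-block level-count imbalance, ties broken by set id.
- **Diagnostics**: per-attribute level counts, overlap rates (fraction of
  sets where both alternatives share a level; warn above 0.5), the maximum
  absolute pairwise correlation of coded columns, and the D-error. Thresholds
  are configurable reporting devices, not hard constraints; a design missing
  them is returned flagged.
- **Dominance set**: a separate attention-check pairing the per-direction
  best level of every attribute against the worst (dominant position
  configurable). Preference directions are an explicit user assertion in the
  catalog; the shipped defaults order levels the way aggregate preferences
  run (higher amounts, cash, consistent schedule, one session/week best and
  three/week worst, healthcare setting).

## Synthetic cohorts

The generator's defaults are the study conditions: three income strata
(150/155/155 respondents → 460 completers), block-stratified assignment
(round-robin within each stratum, so per income × block counts differ by at
most one), ten tasks per respondent (one block), and generating preferences
set to the default preference values — means and SDs per effects-coded column,
money coefficient 0.046 per £10, ASC 1.102, amount interactions +0.065
(middle) and +0.007 (high), ASC interactions +0.067 and +0.363.

Choices are drawn from the three-alternative softmax (a Gumbel-max sampler is
also provided; the two are distributionally identical and tested for
agreement). When the opt-out is drawn, the reported "preferred" program is
the higher-utility program — the survey forces a preference response even
from non-enrollers — and enroll = no.

Aberrant respondents are planted by type: *nontraders* report position A on
every set, *dominance failers* answer the attention check wrongly, and
*never-enrollers* decline every program; defaults plant 3/15/12 in the
460-respondent cohort. Model-driven respondents whose simulated answers
would *by chance* trip a cleaning rule (all-same-position or all-no) are
redrawn (`exclude_chance_aberrant=True`), and planted respondents are redrawn
if they would be attributed to an earlier rule than the planted one. This
makes the planted counts exactly the counts the cleaning cascade recovers,
under any seed. The redraw conditions on an event of probability well under
1% per respondent, so the induced selection bias on choice frequencies is
negligible relative to sampling noise at these scales; it can be disabled.

What the generator does **not** emulate: response times, item nonresponse,
learning or fatigue across the ten tasks, correlated random coefficients, or
any systematic income differences beyond the two interaction terms. Passing
recovery tests therefore demonstrates correctness of the estimator under the
model's own assumptions — not robustness to misspecification on real data.

## Cleaning and descriptives

Three rules apply sequentially, each to the survivors of the previous:
nontraders (same preferred position on *every* task — always-A or always-B;
the symmetric extension of the observed always-A pattern), dominance-check
failers, then never-enrollers. Each removed respondent is attributed to the
first rule that catches them, so counts reconcile exactly. Cleaning is
idempotent.

Enrollment descriptives (share enrolling in all programs, share in none,
share of enroll = yes responses) are computed on the sample *after* the
nontrader and dominance exclusions but *before* the never-enroller exclusion
— the only denominator convention under which both the all-enrollers and the
never-enrollers percentages are consistent with their reported counts.
Percentages display with half-up rounding to two decimals; coefficients to
three.

## Estimation

The simulated log likelihood is

    SLL(θ) = Σ_i log (1/R) Σ_r Π_t P_it(β_ir),   β_irk = b_k + w_k Φ⁻¹(u_irk)

with per-respondent task products computed in log space and max-subtraction
everywhere. Draws `u` are Halton points (radical inverse in the first K
primes, first point at index 1, **skip 100**, R = 500 by default; the
acceptance-scale fits use R = 200), reshaped so each respondent owns a
contiguous block of R points per dimension; pseudo-random uniform draws are
available as an alternative.

- **Gradient**: analytic. With mixture weights
  W_ir ∝ Π_t P_it(β_ir), the score contributions are the usual logit
  residuals aggregated per respondent, weighted by W_ir, and (for w_k)
  multiplied by the respondent-draw normal deviate. The implementation
  processes respondents in chunks to bound memory and is verified against
  finite differences and, for the likelihood itself, against a Gauss–Hermite
  quadrature oracle in one dimension.
- **Optimization**: BFGS from a conditional-logit warm start (means and fixed
  terms at the MNL solution, all SDs at 0.1), gradient tolerance 1e−6, at
  most 500 iterations. The accepted-iterate objective is non-decreasing
  (tested).
- **Identification of SDs**: the likelihood is even in each w_k, so SDs are
  reported as |w_k|; sign flips are checked to leave the likelihood invariant
  (under a sign-symmetrized draw set — with finite, non-antithetic draws the
  invariance is exact only in the population).
- **Standard errors**: inverse negative Hessian, where the Hessian is a
  central finite difference of the analytic gradient (relative step 1e−5); a
  sandwich (robust) variant is available behind a flag. A singular Hessian
  falls back to a pseudo-inverse and flags SEs as unavailable.
- **Degenerate-mixture oracle**: with all w = 0 the SLL equals the
  conditional-logit log likelihood exactly (tolerance 1e−10) for any R —
  this, not another package, is the estimator's primary correctness anchor,
  together with parameter recovery from synthetic truth at n = 2,000,
  R = 200.

The model is wrapped statsmodels-style: `MixedLogit(data, spec)` is the model
object, `fit()` returns `MixedLogitResults` holding estimates, SDs,
covariance, log likelihood and convergence diagnostics, with `summary()`
rendering the level-by-level effects table (omitted levels reconstructed as
negative sums, two-sided normal stars).

## Post-estimation

- **WTA**: `unit · β_term / (−α)` in £ over the whole program, using the
  low-income money coefficient. Positive (desirable) coefficients give
  negative WTA. Intervals use the **Krinsky–Robb** parametric bootstrap:
  draw parameter vectors from N(θ̂, V̂) (default 10,000 draws), evaluate the
  ratio, take percentile bounds; endpoints are additionally presented in
  (closer-to-zero, farther-from-zero) order. Percentile (not bias-corrected)
  intervals; calibration is verified at ~95% coverage for linear quantities
  and against the delta method for ratios in the small-SE regime.
- **Uptake**: P(enroll) for a configured program against the opt-out,
  `E_β[σ(V_program − V_optout)]`, integrated over the fitted coefficient
  distribution with seeded Halton draws (default 2,000), or evaluated at the
  coefficient means (`means_only=True`, closed form). Uptake curves over an
  amount grid share one seed.
- **Indifference amount**: the £ amount solving V(program, amount) = V_optout
  at the coefficient means; closed-form linear solve, cross-checked against a
  root of the means-only uptake curve at 0.5. For a program at the attribute
  means this reduces to `unit · δ_g / α_g`.

A shape caveat worth recording: the cash-minus-voucher uptake *gap* is
guaranteed to shrink with the amount only once both programs' uptake exceeds
one half (the logistic density decreases above its inflection); below that
region the gap can widen as amounts grow — and does, under the default
generating preferences, between £50 and £100. Shape assertions are therefore
made on the above-one-half region.

## Problem sizes and determinism

The packaged fixtures and tests use the survey's natural scales where that is
cheap (460-respondent cohorts, 30-set designs, 4,300 observations) and a
single larger recovery experiment (2,000 respondents × 10 tasks, R = 200) as
the estimator's end-to-end check; interval-calibration experiments use 1,000
replications of 10,000 draws. Every stochastic component takes an explicit
seed; a pipeline master seed expands deterministically into per-stage seeds,
and identical configurations reproduce identical numeric artifacts.

## Known limitations

- Diagonal mixing only; no correlated random coefficients, no lognormal or
  triangular mixing, no WTP-space estimation, no hierarchical Bayes.
- The design search is heuristic (coordinate exchange); it certifies nothing
  beyond beating random designs and its own diagnostics.
- MSL with fixed R is a biased (though consistent as R → ∞) estimator; R is
  a quality knob, and the reported log likelihood is the simulated one.
- Real-data idiosyncrasies (attribute non-attendance, lexicographic choice,
  scale heterogeneity) are neither generated nor modeled.
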