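# Methods

## Model

The package treats a probability-judgment task as a binary-hypothesis
problem with symmetric binary evidence: the focal hypothesis has prior
probability `p`, and each independent piece of evidence confirms it with
probability `l` under the focal hypothesis and `1 − l` under the
alternative. Bayesian updating is additive in natural log-odds,

    LO_posterior = LO_prior + n · ln(l / (1 − l)),

and the Adaptive Bayesian Cognition (ABC) model replaces the unit weights
with attentional ones:

    LO_hat = γ · LO_prior + (λ − γ) · LΛ,   LΛ = n · ln(l / (1 − l)).

`γ` is the attention allocated to the prior and `λ` the total attentional
capacity. The admissible region is `0 ≤ γ ≤ λ`, `1 ≤ λ ≤ 2`; the
one-parameter model is the slice `λ = 1` (fully competitive weighting),
and `(γ, λ) = (1, 2)` is the Bayesian norm. `λ/2` is the threshold
separating conservatism (`γ > λ/2`, prior over-weighted) from base-rate
neglect (`γ < λ/2`); equality within 1e-9 is reported as `balanced`,
since the regime definition itself uses strict inequalities and gives no
tolerance. Reduced capacity under divided attention corresponds to
`λ < 1`; rather than a separate opt-in mode, all bound checking is
disabled with a single `strict=False` flag, which also covers exploratory
regression estimates such as `γ > λ`.

All logarithms are natural (nats). Log-odds of the design-average
posterior confirm this convention: the posterior at prior 0.15 and
likelihood 0.775 is 0.378 with log-odds ln(0.378/0.622) = −0.498.

Evidence is modelled as symmetric and all-confirming: the reference grid
for three pieces of evidence is consistent with three independent
confirming draws (likelihood ratio applied three times), and that is the
only multi-evidence structure implemented. Asymmetric class-conditional
likelihoods and multi-hypothesis updating are out of scope.

### Boundary probabilities

Probabilities are clipped to `[ε, 1 − ε]` with ε = 0.005 before any
log-odds transform — half of one percentage point, the resolution of the
percent response scale, so clipping never moves a rounded response across
a percent boundary. The ε is a parameter of every transform for users who
need a different policy; clipping events are logged.

### Divergence diagnostics

Model mismatch is quantified pointwise across a prior grid as the
Kullback–Leibler divergence between the two Bernoulli posteriors, default
direction KL(Bayes ‖ ABC) with the normative posterior as reference. The
direction is a parameter because either convention is defensible; the
values are asymmetric but the zero set is identical. The default prior
grid is 99 points from 0.01 to 0.99, a figure-style resolution.
For `γ ≠ 1` the ABC and Bayesian log-odds lines cross at
`LO_prior = LΛ · (γ + 1 − λ)/(γ − 1)` (the one point of zero divergence);
at `γ = 1, λ = 1` the lines are parallel and never cross, and at the norm
they coincide everywhere.

## Task battery

The battery crosses three contents (urn, standard cab, modified cab), two
evidence levels (n = 1, 3) and two framings (probability, frequency) into
12 scenario types, and 3 priors {0.1, 0.15, 0.2} × 4 likelihoods
{0.7, 0.75, 0.8, 0.85} into 12 numeric combinations (design averages 0.15
and 0.775). Each participant sees all 12 scenario types and uses each
numeric combination exactly once. The assignment constraint is satisfied
with a cyclic Latin square: a seeded random bijection for the first
participant, shifted by one per subsequent participant, so any cohort
size divisible by 12 is exactly balanced (48 participants → 144 unique
scenario-type × combination pairs, 4 occurrences each); other sizes are
as-equal-as-possible (counts differ by ≤ 1) with a warning. Presentation
order is an independent per-participant shuffle; no interaction between
ordering and balance is imposed. Each participant draws from an independent seeded substream,
so cohorts are reproducible and editing one participant leaves the others
unchanged.

## Synthetic cohorts

The simulator emulates booklet-style percentage judgments. For each
battery row the content's (γ, λ) produce the model log-odds; Gaussian
noise with SD σ is added in log-odds space; the result is mapped to a
probability and emitted as a complementary percent pair. Noise lives in
log-odds space because empirical per-scenario log-odds SDs are nearly
constant across conditions (≈ 0.77–0.95) whereas probability-space noise
would be strongly heteroscedastic; the default σ = 0.9 sits mid-range.
The study-emulating cohort uses γ_urn = 0.9 (the meta-analytic urn-task
range is ≈ 0.90–0.95) and γ_cab = 0.25 with λ = 1 — a low value chosen to
produce the pronounced likelihood-anchoring seen in cab-type scenarios —
for 48 participants.

Realistic imperfections, each independently switchable:

- **Integer-percent rounding** (default on) mimics the response format.
- **Non-normalized pairs**: with probability 0.05 per pair the complement
  is multiplied by a uniform jitter on [0.6, 1.4], so the two percentages
  stop summing to 100 and the scaling correction downstream is exercised.
  The empirical rate of such pairs is not reported; 0.05 is a one-time
  realism choice.
- **Missing pairs**: default rate 1/576 — one blank pair was observed in
  the original 48 × 12 response sheets.

The simulator is framing-blind by default (an optional additive log-odds
shift per framing level exists, default 0): the empirical framing effect
has no stated generative mechanism, so the generator does not assert one.
Passing tests on these cohorts therefore demonstrates internal
consistency of the pipeline under the stated response model — they cannot
show that real judgments follow the ABC model, only that if they do, the
pipeline measures it correctly. Sequential within-trial belief dynamics
and response styles (digit preference, end-aversion) are not modelled.

## Preprocessing

Pairs are normalized by the scaling factor `1/(p1 + p2)`; the subjective
log-odds are `ln(p1/p2)` after ε-clipping. Missing pairs are imputed by
the component-wise mean of the other participants' *normalized* pairs for
the same scenario type (probability-space averaging, then
renormalization); unscalable pairs (sum 0) are treated as missing.
Classification compares the normalized focal response to three references
— prior, Bayesian posterior, single-draw likelihood — with a ±0.03 band.
Bands can overlap (e.g. prior 0.2, posterior 0.206 for a hypothetical
cell); the nearest reference wins, with exact ties broken by the fixed
priority posterior > prior > likelihood. Classification is restricted to
single-evidence scenarios, where the three references are unambiguous.
Whether the original classification used raw or normalized responses is
unstated; normalized is adopted.

Cohort summaries report two Bayesian benchmarks side by side, because
they genuinely differ: `p_bayes_design` evaluates the posterior at the
cohort-average prior and likelihood (0.378 / 0.878 for n = 1 / 3 in the
balanced battery — the conventional reference-table values), while
`p_bayes_mean` averages the record-level posteriors over the numeric
combinations actually presented (0.382 / 0.844 under full balance, by
Jensen's inequality not equal to the former). An ideal Bayesian cohort
reproduces the record-level benchmark exactly, which is what the
pipeline-identity test asserts; the design-level columns match the
conventional references.

## Estimation

Because the forward model is linear in log-odds, estimation is ordinary
least squares (homoscedastic log-odds noise is the generative
assumption; robust or weighted variants are out of scope):

- one-parameter model: `y − LΛ = γ (x − LΛ)` through the origin, closed
  form `γ̂ = Σxy/Σx²`, clipped to [0, 1] with the raw value retained;
- generalized model: no-intercept regression of `y` on `(x, LΛ)` with
  `γ̂ = b₁`, `λ̂ = b₁ + b₂`; identification requires independent variation
  of prior and evidence strength (the balanced battery provides it; a
  rank-deficient design raises with a message naming the missing
  contrast). Raw estimates outside the admissible region trigger a
  bounded SLSQP refit; both raw and constrained values are reported.
  Raw coefficients within 1e-9 of a bound are snapped to it rather than
  refit (floating-point slack).

Context-specific parameters are obtained by fitting per content subset;
per-participant fits are independent (no hierarchical shrinkage).
Recovery experiments run simulate → preprocess → fit on clean cohorts
(no imperfections, rounding off by default, so noiseless recovery is
exact) and report bias, RMSE and nominal-95%-interval coverage of γ̂. At
σ = 0.9 with 48 participants × 12 trials the pooled estimator is
unbiased well within 0.02 and RMSE scales as 1/√n. Default problem
sizes — 200 replicates at 48 and 192 participants — keep a full recovery
study under a minute on one core.

## Power planning

One-sample *t*-test power is computed exactly under the noncentral *t*
distribution (noncentrality δ√n, df n − 1), not a normal approximation:
the planning values — minimal n of 44 (two-tailed) and 36 (one-tailed)
for power ≥ 0.9 at |δ| = 0.5, α = 0.05 — are reproduced only by the exact
calculation. Minimal n is found by doubling bracket plus binary search on
the monotone power curve.

## Known limitations

- The generator produces one-shot judgments; sequential updating (where
  today's posterior becomes tomorrow's prior and γ-misweighting
  compounds) is not modelled.
- The ±0.03 classification is a hard partition; graded membership or
  mixture modelling of response modes is not attempted.
- Estimation is point estimation; posterior inference over (γ, λ) and
  hierarchical participant-level models are out of scope.
- Figures are not rendered; mapping and divergence curves are exported as
  delimited text for external plotting.
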