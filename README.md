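# abcog

Toolkit for modelling **probability-judgment biases as context-weighted
Bayesian updating**.

When people judge the probability of a hypothesis from a base rate and a
piece of evidence — "15% of the urns are blue; blue urns contain 80% blue
balls; a blue ball was drawn; how likely is a blue urn?" — their answers
deviate from Bayes' theorem in two famously opposite ways. In statistical
"small-world" tasks (urns) they under-use the evidence (*conservatism*);
in realistic "large-world" scenarios (the taxicab eyewitness problem) they
under-use the base rate (*base-rate neglect*). The Adaptive Bayesian
Cognition (ABC) model casts both biases as a single attention-allocation
mechanism operating in log-odds space:

```
LO_posterior = γ · LO_prior + (λ − γ) · LΛ_evidence
```

where `LO_prior = ln(p/(1−p))` is the prior log-odds, `LΛ_evidence` is the
log likelihood ratio of the evidence, `γ ≥ 0` is the attentional weight on
the prior and `λ ∈ [1, 2]` the total attentional capacity. `γ > λ/2`
produces conservatism, `γ < λ/2` base-rate neglect, and `(γ, λ) = (1, 2)`
recovers exact Bayesian updating. The one-parameter model fixes `λ = 1`,
making prior and evidence compete for a unit budget of attention.

The package provides, as plain Python functions plus a thin `abcog` CLI:

- exact Bayesian updating for symmetric binary-evidence problems
  (`abcog.bayes`), including the full posterior reference grid of the
  3-prior × 4-likelihood × 2-evidence battery;
- the ABC forward model, regime classification and prior-to-posterior
  mapping curves (`abcog.model`);
- pointwise Bernoulli Kullback–Leibler divergence between Bayesian and ABC
  posteriors (`abcog.divergence`);
- a balanced factorial battery generator — every participant sees each of
  the 12 scenario types and each of the 12 numeric combinations exactly
  once, balanced across the cohort by a cyclic Latin square
  (`abcog.design`);
- a synthetic-cohort simulator with per-content (γ, λ), log-odds response
  noise, percent rounding, non-normalized and missing pairs
  (`abcog.simulate`);
- preprocessing of percentage-judgment pairs: scaling correction,
  imputation, subjective log-odds, response-mode classification and
  cohort summary tables (`abcog.preprocess`);
- least-squares estimation of (γ, λ) with parameter-recovery experiments
  (`abcog.estimate`), and exact noncentral-*t* power planning
  (`abcog.power`).

## Worked example

```python
>>> from abcog import ABCParams, bayes_posterior, abc_posterior, regime
>>> bayes_posterior(0.15, 0.80, 1)        # prior 0.15, diagnosticity 0.80
0.4137931034482759
>>> abc_posterior(0.15, 0.80, 1, ABCParams(gamma=0.9))   # urn-like weighting
0.19426815938087738
>>> abc_posterior(0.15, 0.80, 1, ABCParams(gamma=0.25))  # cab-like weighting
0.6470439113650821
>>> regime(ABCParams(0.9)), regime(ABCParams(0.25))
('conservatism', 'base_rate_neglect')
```

The Bayesian answer is 0.414; a conservative responder (γ = 0.9) stays
anchored near the 0.15 prior, while a base-rate-neglecting responder
(γ = 0.25) lands near the 0.80 evidence diagnosticity.

Simulating a 48-participant cohort with urn-conservative and
cab-neglecting contexts, then fitting γ per content, recovers the
generating regimes from the synthetic judgments:

```python
>>> from abcog import study_like_cohort, preprocess_cohort, fit_by
>>> design, judgments = study_like_cohort(seed=7)
>>> fit_by(preprocess_cohort(judgments), by=("content",))[
...     ["content", "gamma_hat", "gamma_se", "n_obs"]]
        content  gamma_hat  gamma_se  n_obs
0  cab_standard   0.229831  0.014742    192
1  cab_modified   0.260389  0.013753    192
2           urn   0.919208  0.013377    192
```

(generating values: γ_urn = 0.9, γ_cab = 0.25, λ = 1, noise SD 0.9).
A recovery experiment quantifies estimator quality:

```python
>>> from abcog import recovery_experiment
>>> r = recovery_experiment(ABCParams(0.9), sigma=0.9, n_participants=48,
...                         replicates=50, seed=7)
>>> print(f"bias {r.bias_gamma:+.4f}  rmse {r.rmse_gamma:.4f}  coverage {r.coverage_gamma:.2f}")
bias +0.0002  rmse 0.0082  coverage 0.94
```

The same operations are available from the shell, e.g.
`abcog design -n 48 --seed 7 --out design.csv`,
`abcog power --delta 0.5 --tails two`, or `abcog run --out results/` for
the full design → simulate → summarize → fit pipeline with a manifest.

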