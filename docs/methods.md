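# Methods

## The model

`msocc` estimates territory occupancy and breeding-success dynamics from
multi-season, multi-state detection histories. Each site (territory) has a
latent seasonal state

* `0` — unoccupied,
* `1` — occupied without successful reproduction,
* `2` — occupied with successful reproduction,

assumed constant within a season (closure) and evolving between seasons as a
Markov chain. Writing ψ_t[m] for the probability a territory is occupied in
season t given previous state m, and R_t[m] for the probability of breeding
success given occupancy and previous state m, the transition row from state m
is

    ( 1 − ψ[m],  ψ[m]·(1 − R[m]),  ψ[m]·R[m] ).

The first season uses unconditional parameters ψ1 and R1 (no previous state
exists). Observation is imperfect but free of false positives: at survey j a
state-1 territory is detected with probability p[1]_j; a state-2 territory is
detected with probability p[2]_j and, if detected, shows evidence of
reproduction with probability δ_j. δ_1 is structurally zero — evidence (eggs,
chicks) cannot exist at the courtship-stage survey — so a successful territory
can never produce code 2 at survey 1. Missing surveys contribute a likelihood
factor of 1.

The site likelihood marginalizes over all latent state paths with the forward
algorithm, multiplying within-season survey factors (closure makes surveys
conditionally independent given the state) and propagating between seasons
through the transition rows. Accumulation uses per-season rescaling of the
forward vector with the log of the normalizer banked, so 28-survey histories
cannot underflow; a history that is impossible under the no-false-positive
structure yields −∞ exactly.

## Covariates and design matrices

ψ and R are logit-linear in covariates. Site covariates are the binary
`zone` and the quantitative `ruggedness`, `crops`, `scrub`, `distance`;
quantitative covariates are standardized to mean 0, sd 1 (sample sd, ddof=1)
before fitting, with the constants retained for reporting. Two structural
covariates exist for the transition families only:

* `state` — the previous latent state, coded as a 3-level categorical with
  two dummies (states 1 and 2 against reference 0). A single ordinal slope
  would force the three reoccupation curves onto a common spacing; the
  categorical coding lets ψ[0], ψ[1], ψ[2] float freely and is the coding
  under which the parameter counts of the reference analysis (K = 25 for
  ψ(State) with R(Year+State+Ruggedness) and survey-specific detection) come
  out right.
* `year` — the transition season as a categorical with the first transition
  as reference, its baseline absorbed by the family intercept.

Detection is parameterized as four free logit-scale values per survey for
each of p[1] and p[2], three free values for δ (surveys 2–4), all constant
across years. Free-parameter bookkeeping for the headline model: ψ1 (1) +
R1 (1) + ψ intercept + 2 state dummies (3) + R intercept + 5 year dummies +
2 state dummies + ruggedness (9) + p[1] (4) + p[2] (4) + δ (3) = 25.

## Estimation

Coefficients are estimated by maximum likelihood with L-BFGS-B on the
unconstrained logit scale. Occupancy likelihoods can be multimodal, so the
fit runs from a zero start, any user-supplied start, and (by default) 10
random starts drawn U(−2, 2) from a fixed seed (20170411), keeping the best
optimum; convergence uses `ftol = 1e-10` on the objective. The
variance–covariance matrix is the inverse of a central-finite-difference
Hessian (step 1e-5 per coordinate, O(step²) accurate) — robust at these
dimensions (K ≤ ~30). A singular or non-finite Hessian marks the covariance
unavailable rather than failing the fit; estimates with any fitted
probability within 1e-6 of 0 or 1 carry a `boundary` flag because Wald
standard errors are unreliable there.

Real-scale probabilities use the delta method on the logit scale; 95%
intervals are Wald intervals on the logit scale back-transformed through the
inverse logit, which keeps them in [0, 1] and produces the expected asymmetry
near the boundaries. The "average occupancy" (and "average success")
summaries average the model-implied *marginal* state distribution — obtained
by propagating (1−ψ1, ψ1(1−R1), ψ1R1) through the transition rows — over
every site-season cell, with uncertainty propagated by a numeric-gradient
delta method.

## Model selection and averaging

Candidates are ranked by AIC; ΔAIC is the difference from the best model and
Akaike weights are exp(−Δ/2) normalized over the candidate set. Ties break
toward smaller K, then label. Because fitting every ψ × R combination is
combinatorial, selection can run in two phases: optimize ψ structure with R
held at an anchor structure, then fix the winning ψ and optimize R. Models
within 2 AIC of the best are reported as alternatives, flagged
non-competitive when their deviance does not improve on the best model's
(the uninformative-parameter signature: ΔAIC < 2 bought entirely by the
extra parameter).

Model-averaged estimates combine per-model points θ_i with weights w_i;
the unconditional standard error Σ w_i √(var_i + (θ_i − θ̄)²) adds
between-model disagreement to within-model variance (Burnham–Anderson).
Averaging defaults to all converged candidates; a mode restricted to the
ΔAIC < 2 subset (weights renormalized) is provided for comparison — the two
agree to well within reporting precision whenever the top models carry
nearly all the weight, which is why published values cannot distinguish the
conventions.

## The synthetic-data generator

`simulate()` draws data with exactly the structure the likelihood assumes,
emulating the owl territory-monitoring design: 72 sites, 7 seasons, 4
surveys per season; `zone ~ Bernoulli(49/72)` (the north/south split of the
monitored territories); quantitative covariates drawn standard normal
directly on the standardized scale, since the analysis only ever sees
standardized values. Default generating coefficients put the reoccupation
probabilities at ψ[0]/ψ[1]/ψ[2] = 0.53/0.85/0.98, detection at
p[1] = (.75,.64,.50,.28), p[2] = (.70,.89,.95,.96), δ = (0,.02,.29,.93) —
the headline operating point of the reference owl study — with first-season
ψ1 = 0.90, R1 = 0.70, success near 0.4–0.8 with ±0.5–1.2 logit year swings
and a −0.64 ruggedness slope. Missingness masks 5% of survey cells at
random (field monitoring rarely completes every visit; the exact rate is a
design choice). Everything is reproducible from a single seed; replicate
seeds in the recovery study derive from it by fixed offsets.

What the generator does *not* emulate: spatial correlation between
territories, observer heterogeneity, year-varying detection, or covariate
measurement error. Passing recovery tests therefore demonstrates internal
consistency of estimator and generator under the model's own assumptions,
not robustness to their violation in field data.

## Numerical and testing choices

* The forward algorithm is verified against an independent brute-force
  enumeration over all 3^T latent paths (tolerance 1e-10).
* With perfect detection (p = δ = 1) the latent states are fully observed
  and ML transition probabilities must equal empirical conditional
  frequencies; this reduction is asserted to 1e-3 (optimizer tolerance).
  In that regime detection logits drift toward +∞ along flat likelihood
  directions; estimates of ψ/R are unaffected.
* The calibration (recovery) study fits each replicate from the zero vector,
  the generating truth and one random start — these designs produce a
  well-behaved optimum and the warm start keeps a replicate cheap. The
  calibration suite runs 100 replicates at 500 sites × 7 seasons; the
  acceptance script's quicker summary uses 40 replicates at 200 sites.
* Degenerate inputs: a site with every survey missing is rejected at
  validation (its likelihood carries no information and breaks naïve
  denominators); a constant quantitative covariate is a standardization
  error naming the covariate; condition covariates absent from a model's
  terms raise a specification error.

## Known limitations

* Standard errors are asymptotic (Wald); no profile or bootstrap intervals.
* No false-positive observation extension, no within-season state change,
  no random effects; AIC only (no AICc/BIC) — matching the model class the
  package implements.
* Detection structure is fixed at survey-specific, year-constant p[1], p[2],
  δ with δ1 = 0; alternative detection structures would require extending
  the design layer.
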