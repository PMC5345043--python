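# Methods

`healthtrait` constructs a single 0–100 metric of health from
heterogeneous ordinal health items observed over several waves of a
longitudinal ageing cohort, and validates it against covariates and hard
outcomes. This note records the models, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## The measurement model

Items are ordinal with 2–5 categories, coded 0-based with **higher =
worse health**. For person *p*, wave *w*, item *i* with K<sub>i</sub>
categories, the graded normal-ogive (probit) model is

```
P(X_pwi >= k | theta_pw) = Phi(a_iw * theta_pw - b_iwk),   k = 1..K_i-1
theta_pw = u_w + e_pw,   u_w ~ N(0, sigma_u^2),   e_pw ~ N(0, sigma_theta^2)
```

`theta` measures *ill*-health internally; the sign is reversed only in the
final 0–100 transform (`score = 100 (theta_max - EAP) / (theta_max -
theta_min)`, pooled min/max, clamped for out-of-sample values).

Anchor items (fielded in every wave) carry the common scale; wave-varying
items may be absent from some waves. Item parameters may drift across
waves; four nested variance configurations are supported:

| config | wave-level structure |
|---|---|
| M1 | none: `a_iw = a_i`, `b_iwk = b_ik` |
| M2 | `b_iwk = b_ik + d_iw`, `d_iw ~ N(0, sigma_b_i^2)` per item |
| M3 | as M2 with one shared `sigma_b^2` |
| M4 | M2 plus `a_iw ~ N(a_i, sigma_a_i^2)` and hierarchical priors `a_i ~ N(mu_a, tau_a^2)`, `b_ik ~ N(mu_b, tau_b^2)` with estimated hyperparameters |

Identification follows the mean-slope rule: after every sweep the chain is
rescaled so the mean item slope equals one exactly (slopes divided,
abilities/wave effects/SDs multiplied), leaving the likelihood invariant.
Persons do **not** get a random effect inside the IRT: longitudinal
dependence is handled downstream by the mixed model, keeping the two-stage
architecture.

### Sampler

Markov chain Monte Carlo with:

* truncated-normal data augmentation for the latent response process
  (`Z_pwi ~ N(a_iw theta_pw, 1)` truncated between the thresholds of the
  observed category), giving conjugate normal updates for abilities, wave
  effects and slopes;
* Metropolis-within-Gibbs for the ordered category thresholds and the
  scalar wave offsets `d_iw`, evaluated on the collapsed ordinal
  likelihood (a partially collapsed scheme: thresholds move first in each
  sweep and the augmented data are redrawn immediately afterwards, which
  keeps the stationary distribution intact). Joint random-walk proposals
  per item; non-monotone proposals are rejected, so threshold ordering
  holds in every retained draw. Proposal SDs are auto-tuned during
  burn-in to a 20–50% acceptance window;
* inverse-gamma updates for all variances; truncation (> 0) of item-level
  slopes.

Priors (weakly informative, overridable in `MLIRTSpec`): slopes
N(1, 2) truncated positive, thresholds N(0, 4), variances
InverseGamma(1, 1), M4 hyper-means N(·, 10). Missing cells are skipped
(MAR). Default chain settings are 5,000 iterations with 100 burn-in;
because such a short burn-in is optimistic, a Geweke diagnostic on the
retained deviance chain (|z| > 3) triggers discarding the first half of
the retained draws with a logged warning. A divergence guard aborts if
any |theta| exceeds 50.

Scoring and fit summaries: per person-wave EAP and posterior SD; EAP
reliability `Var(EAP) / (Var(EAP) + mean posterior variance)`; DIC with
`pD = Dbar - D(posterior means)`; wave-level ICC
`sigma_u^2 / (sigma_u^2 + sigma_theta^2)` summarised by the posterior
median and central 95% interval (the ability-variance definition — the
score-variance alternative was the other candidate; the ability ratio is
the quantity the model parameterises directly). Model comparison ranks by
highest EAP reliability and lowest DIC, flags disagreement, and breaks
ties (and disagreements) toward lower DIC.

## Unidimensionality screen

* **Polychoric correlations**: two-step — thresholds from inverse-normal
  cumulative marginals, then a bounded 1-D likelihood maximisation over
  bivariate-normal rectangle probabilities, computed exactly via Owen's T
  function. Pairwise-complete estimation; nearest-PSD smoothing
  (eigenvalue clipping + rescaling) applied only when needed, with a flag.
  Pairwise estimation replaces full-information missing-data handling;
  with item-level missingness capped at 25% per person the pairwise bias
  is small. Estimates clamp to [-0.999, 0.999].
* **MAP test** (Velicer): average squared partial correlation after
  removing successive principal components; minimising m wins, ties to the
  smaller m.
* **EFA**: minimum-residual extraction (L-BFGS over uniquenesses started
  at 1 − SMC), Heywood cases clamped with a warning; **geomin** oblique
  rotation (epsilon = 0.01) by gradient projection from the identity plus
  9 seeded random starts, best criterion kept.
* **Item assignment**: every factor with |loading| >= 0.25 (ties at the
  cutoff included).
* **Second-order CFA**: standardized first-order factors with correlation
  matrix `gamma gamma' + diag(1 - gamma^2)` induced by one general factor;
  estimated by unweighted least squares over all unique moments of the
  correlation matrix (bounded trust-region least squares). The chi-square
  is the ML discrepancy at the ULS solution times (N − 1); CFI/TLI against
  the independence baseline; RMSEA `sqrt(max(chi2 - df, 0)/(df (N-1)))`
  with a 90% CI from inverting the noncentral chi-square. This replaces a
  weighted categorical least-squares estimator with a full asymptotic
  weight matrix: indices are comparable in behaviour, not in exact value,
  and the ML-form chi-square is only trustworthy at factor-analysis-scale
  samples (hundreds upward); on very small validation splits it inflates.

## Downstream validation

* **Crossed mixed model** `y = X beta + alpha_person + gamma_wave + eps`
  by maximum likelihood (not REML, so the LRT vs OLS and AIC are
  coherent): beta and the residual variance are profiled out; the two
  variance ratios are optimised on the log scale (Nelder-Mead) with the
  Woodbury identity on the person+wave indicator design, so cost scales
  with group counts. Verified to match `statsmodels` MixedLM
  (crossed variance components) to ~1e-4 in log-likelihood. Wave effects
  are crossed with persons, not nested. Boundary estimates
  (ratio < 1e-6) are flagged; the LRT keeps the naive chi-square(2)
  reference, which is conservative at the boundary.
* **Adjusted McFadden pseudo-R²**: `1 - (ll_full - k_full)/ll_null`.
* **Conditional ICC**: `(sd_person^2 + sd_wave^2) / (total)`.
* **ROC/AUC**: Mann-Whitney with ties at 1/2 and DeLong variances.
  Orientation: lower health score predicts the adverse outcome, so the
  negated score enters the ROC. "Adjusting by gender" is operationalised
  as the case-control-pair-weighted average of within-gender AUCs with a
  stratified DeLong variance (the adjustment is not defined more precisely
  in the source methodology; this choice is recorded prominently). The
  two-marker comparison is the paired DeLong test on common subjects,
  stratified the same way.
* **Pattern mining**: scores binned at (-inf,20], (20,40], (40,60],
  (60,inf) into classes 1–4; bagged entropy trees (scikit-learn trees;
  bagging, OOB bookkeeping, permutation MDA and path extraction in
  package code). MDA is the OOB-accuracy drop (×100) when one feature is
  permuted, averaged over permutations — a raw accuracy-point scale, not
  the SD-scaled importance some implementations report. Patterns are
  root-to-leaf paths of 100 seeded shallow trees (bootstrap rows, random
  per-split feature subsets, `mtry = ceil(sqrt(p))`, `min_leaf = 20` so
  rules stay supported); a path's accuracy is its confidence for its
  predicted class, evaluated on the full sample (a config switch allows
  OOB-only evaluation); rules below 40% are dropped (a uniform random
  4-class classifier scores 25%), the five most accurate per class are
  kept (ties: larger support, then fewer conditions).

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 45 ordinal
items (2–5 categories, cycled), 5 first-order factors under a general
factor (round-robin item assignment, 3 cross-loading items), 6 waves, 6
wave-varying items (fielded at baseline, absent from at least one later
wave), item-level MCAR missingness (default 5%) with the baseline 25%
per-person cap enforced, wave-level drift in thresholds (SD 0.30) and
slopes (SD 0.15) — drift magnitudes are free parameters, not calibrated
values, since the source study does not report them — wave effect SD 0.7
and person-wave residual SD 0.7 (true wave-level ICC 0.5), ten ordinal
covariates with independent multinomial marginals, and probit outcomes of
centred baseline ill-health.

Calibrated-once defaults: the mortality slope (0.50 at 20% base rate) and
chronic-condition slope (0.15) were solved from the latent model so the
oracle AUCs sit near 0.73 (score) and 0.56 (condition count), the study
conditions the validation stage is meant to reproduce; the physical
activity effect (0.80 per level) makes it the dominant determinant, the
structure the importance analysis is specified to detect. The
institutionalisation base rate is 5% — a realistic institutionalisation
rate of ~1% would leave a handful of cases at desk-scale n and make every
downstream statistic degenerate.

What the generator does *not* emulate: realistic marginal distributions
of a real ageing cohort, informative (non-MCAR) missingness, survey
weights, or dependence between covariates. Passing recovery tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to the violations real data bring.

## Problem sizes

All simulations are sized for a single desktop core. Parameter-recovery
and model-selection experiments use 5 seeded replicates (n = 250–300
persons, 12–20 items, 700–1,200 MCMC iterations); success proportions
required by the tests (at least 4 of 5) preserve the 90% proportion of
the full-scale design (18 of 20). The acceptance script runs one
500-person cohort with 1,000-iteration chains for M1 and M4, a
2,000-person five-factor ordinal sample for the MAP test, and the two
closed-form worked examples. MCMC Monte-Carlo error at these chain
lengths is roughly ±0.01 on EAP reliability and ±0.05 on the wave ICC
median.

## Known limitations

* The ML-form chi-square after ULS estimation is not the WLSMV statistic;
  absolute fit values are not comparable to software using categorical
  robust estimators.
* With 6 waves the wave-variance posterior is wide and prior-sensitive
  (InverseGamma(1,1)); the wave ICC median on 6-wave cohorts sits above
  the generating 0.5 by up to ~0.15.
* Threshold Metropolis moves mix more slowly than the conjugate blocks;
  very short chains (a few hundred sweeps) can understate threshold
  uncertainty.
* The pattern-accuracy filter evaluates on the full sample by default,
  which is optimistic relative to held-out evaluation; the OOB switch
  trades support for honesty.
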