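# healthtrait

Construction and validation of a single **0–100 metric of health** from
heterogeneous ordinal health items collected over several waves of a
longitudinal ageing study — the kind of panel where functioning, mobility,
sensory, cognitive and emotional items (2–5 ordered categories each) are
asked repeatedly, some items are dropped or added between waves, and the
goal is one score per person per wave that is comparable across waves.

It is written for biostatisticians and epidemiologists who need to

1. **screen** baseline items for essential unidimensionality
   (polychoric correlations, Velicer's MAP test, minres EFA with oblique
   geomin rotation, second-order CFA with CFI/TLI/RMSEA);
2. **calibrate** a Bayesian multilevel graded normal-ogive IRT model in
   which anchor items (asked in every wave) carry the common scale while
   wave-varying item parameters drift:

   P(X_pwi ≥ k | θ_pw) = Φ(a_iw·θ_pw − b_iwk),  θ_pw = u_w + e_pw,
   u_w ~ N(0, σ_u²), e_pw ~ N(0, σ_θ²),

   estimated by MCMC (truncated-normal data augmentation, conjugate
   updates, Metropolis threshold moves), identified by fixing the mean
   item slope to one, scored by EAP, compared across four variance
   configurations via EAP reliability and DIC, and mapped to 0–100
   (higher = better health);
3. **validate** the score: crossed person×wave random-intercept mixed
   model (ML), likelihood-ratio test against OLS, adjusted McFadden
   pseudo-R², conditional ICC, criterion-validity regression,
   gender-adjusted ROC/AUC with paired DeLong comparison against a simple
   chronic-condition count, and tree-ensemble pattern mining (permutation
   MDA importance, 40%-accuracy decision rules).

Because access-restricted cohort microdata cannot ship with code, the
package includes a first-class synthetic-cohort generator
(`healthtrait.synthetic`) reproducing the full assumed structure — 45
items on 5 correlated factors under a general factor, 6 waves, 39 anchor
+ 6 wave-varying items, MCAR missingness, covariates and probit outcomes
— with all ground truth retained for recovery testing.

See `docs/methods.md` for the models, priors, numerical choices and
limitations.

## Worked example

```python
from healthtrait.config import GeneratorConfig
from healthtrait import irt, item_prep
from healthtrait.synthetic import generate_cohort

cohort = generate_cohort(GeneratorConfig(n_persons=500, seed=1))
panel, pw = item_prep.filter_personwave_irt(cohort.panel)   # > 1/2 missing out

fits = {}
for model in ("M1", "M4"):
    spec = irt.MLIRTSpec(variance_config=model, n_iter=1000, burn_in=250, seed=1)
    post = irt.fit_mlirt(panel, cohort.catalog, spec, pw_mask=pw)
    fits[model] = (irt.eap_reliability(post),
                   irt.dic(post, panel, cohort.catalog)[0])
    if model == "M4":
        m4 = post

print(irt.compare_models(fits)["table"])
icc, ci = irt.wave_icc(m4)
scores, transform = irt.to_health_score(irt.eap_scores(m4))
print(f"wave ICC {icc:.2f} {ci}, |r| vs sum score "
      f"{irt.sumscore_correlation(scores, panel):.2f}")
```

prints (seed 1):

```
{'M1': {'eap_reliability': 0.9359, 'dic': 173916.6}, 'M4': {'eap_reliability': 0.9307, 'dic': 171193.0}}
wave ICC 0.73 (0.52, 0.91), |r| vs sum score 0.95
```

Reading: the hierarchical model M4 wins on DIC (the generator drifts item
parameters across waves, which M1 ignores); EAP reliability ≈ 0.93 means
the 45 items measure the latent trait precisely; the wave-level ICC says
that over half of ability variance sits between waves (the generating
ratio is 0.5; with only six waves the posterior is wide and its median
sits high); and the 0–100 metric correlates |r| ≈ 0.95 with the naive
mean of the recoded items while properly handling missing and
wave-varying items.

A command-line interface mirrors the stages:

```bash
healthtrait simulate --seed 1 --out cohort/
healthtrait irt --responses cohort/responses.csv --catalog cohort/catalog.json \
    --model M4 --n-iter 1000 --burn-in 250 --out irt_out/
healthtrait run --seed 1 --out full_run/       # entire pipeline
```

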