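# normnet

Tools for studying how adolescent school friendship networks relate to
smoking social norms across two survey waves. The package targets the common
design of school-based smoking-prevention studies: every student in a year
group nominates up to ten closest friends at baseline and follow-up, answers
self-report and incentivized survey items measuring *descriptive* norms
(beliefs about what others do) and *injunctive* norms (beliefs about what
others approve of), and schools receive either a peer-led or a teacher-led
intervention.

`normnet` implements the full analysis chain:

1. **Norm scores** — raw Likert items are aligned onto [0, 1]
   (0 = against smoking, 1 = favorable), aggregated into constructs with
   Cronbach's-alpha reliability checks, and reduced to one latent
   descriptive and one latent injunctive score per student per wave with a
   one-factor maximum-likelihood measurement model.
2. **Feature-saliency mixture clustering** — an exploratory Gaussian mixture
   in which feature *l* is, with component-specific probability ρ_jl,
   drawn from component *j*'s own Gaussian and otherwise from a shared
   background density:

   p(y | Θ) = Σ_j α_j Π_l [ ρ_jl p(y_l | θ_jl) + (1 − ρ_jl) q(y_l | ϑ_l) ]

   estimated by a conjugate Gibbs sampler (Dirichlet / Beta /
   Normal-Inverse-Gamma priors).
3. **Latent transition analysis** — a two-wave latent Markov model with
   Gaussian class profiles shared across waves (measurement invariance),
   initial distribution π and transition matrix τ, fitted by multi-start
   EM, with BIC class selection and a relative-entropy classification
   certainty statistic.
4. **Covariate profiling** — baseline-category multinomial logistic
   regression of the latent groups on sociodemographic and psychosocial
   covariates, with odds ratios, Wald 95% CIs and explicit separation
   reporting.
5. **Network change** — per-wave summaries (mean in-degree = ties/nodes,
   density = ties/(n(n−1))) and the Jaccard tie-change index
   J = A11 / (A01 + A11 + A10) with the gradual-change band [0.3, 0.6].
6. **STERGM homophily** — a separable temporal exponential random graph
   model: tie formation (over supersets of the earlier network) and tie
   dissolution (over subsets) with edges, reciprocity, transitive-ties and
   norm-side homophily statistics, estimated by maximum pseudolikelihood,
   plus a Gibbs simulator for simulate-then-estimate checks.
7. **Influence descriptives** — ego transition categories
   (maintain/change × favorable/against), tie partition into
   persisting/new/dropped, friend-composition profiles, the baseline
   favorable-friend *network threshold* comparison, and a chi-square of
   transition-to-against by intervention arm.

Because cohort data of this kind is not publicly deposited, the package
includes a first-class synthetic cohort generator
(`normnet.synthetic`) that emulates the study scale — 12 schools of 77–177
students, mean in-degree ≈ 6.5, between-wave Jaccard in the gradual-change
band, three norm groups at ≈ 11% / 86% / 2% prevalence — with *tunable*
homophily, reciprocity, peer influence and intervention effects, so every
stage can be validated against planted ground truth.

## Worked example

```python
import numpy as np, pandas as pd
from normnet import (CohortConfig, generate_study, build_norm_scores,
                     fit_lta, wide_scores)

study = generate_study(CohortConfig(n_schools=4, school_size_range=(90, 120), seed=3))
table = pd.concat([t for t, _ in study], ignore_index=True)
wide = wide_scores(build_norm_scores(table))
model = fit_lta(wide[["descriptive_t0", "injunctive_t0"]].to_numpy(float),
                wide[["descriptive_t1", "injunctive_t1"]].to_numpy(float),
                3, n_restarts=10, seed=0)
for k, label in enumerate(model.class_labels):
    print(label, np.round(model.means[k], 2), round(model.pi[k], 2))
print(np.round(model.tau, 2), round(model.relative_entropy, 2))
```

prints:

```
injunctive-favorable [0.43 0.88] 0.03
both-against [0.18 0.15] 0.87
descriptive-favorable [0.79 0.2 ] 0.1
[[0.67 0.33 0.  ]
 [0.01 0.95 0.05]
 [0.   0.41 0.59]] 1.0
```

— the three norm groups emerge at their planted prevalences (≈ 87% both
against, ≈ 10% descriptive-favorable, ≈ 3% injunctive-favorable), the
against-group is highly persistent (τ = 0.95 on its diagonal), roughly 40%
of each favorable group reverts to against between waves (the generator's
planted intervention-plus-reversion regime), and the classification
certainty is essentially 1 in this well-separated setting.

The `examples/` directory holds one short narrative script per capability
(cohort simulation, norm scores, latent groups, network change + STERGM,
influence descriptives). A thin CLI mirrors the pipeline:

```bash
normnet simulate --seed 1 --out cohort/
normnet run --seed 1 --out run1/            # full synthetic pipeline
normnet run --attributes cohort/attributes.csv --edges cohort/edges.csv --out run2/
```

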