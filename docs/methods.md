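# Methods

This note documents the models behind `normnet`, the choices that were
genuinely open, and what the synthetic cohort does and does not emulate.

## The scientific setting

Two-wave school friendship networks: each student in a year group nominates
up to ten closest friends before and after a smoking-prevention
intervention (peer-led or teacher-led), and answers self-report and
incentivized items measuring descriptive and injunctive smoking norms. The
analysis asks whether *homophily* (befriending students with similar norms)
or *social influence* (norms drifting toward those of one's friends)
shapes the co-evolution of the friendship network and the norm groups.

## Norm scores

Items are aligned onto [0, 1] with the affine map (x − min)/(max − min)
after reverse-coding, so 0 always means "against smoking" and the scale
endpoints land exactly on 0 and 1. (Dividing by the maximum alone would
leave a nonzero floor for items whose minimum is not 0; the affine map is
the convention consistent with scores spanning the full unit interval.)
"I don't have one" responses become missing and construct means are taken
over the available relationships. Construct reliability is summarized with
Cronbach's alpha, α = k/(k−1)·(1 − Σ var(item)/var(total)), on complete
rows.

One latent score per norm type is obtained from a single-factor
maximum-likelihood factor model (`sklearn.decomposition.FactorAnalysis`)
over the constructs; factor scores use the regression (posterior-mean)
method. Two conventions the measurement literature leaves open here:
loadings are estimated **per wave** (pooling both waves is a one-line
change), and scores are min-max rescaled to [0, 1] per sample so the
latent scale matches the item scale. Complete-case analysis throughout: a
student enters the longitudinal models only with both scores at both
waves; no imputation.

## Feature-saliency mixture (exploratory clustering)

A K-component diagonal Gaussian mixture in which each feature has a
component-specific *saliency* ρ_jl — the probability that feature l of a
point in component j comes from the component's own Gaussian rather than a
shared background Gaussian:

p(y | Θ) = Σ_j α_j Π_l [ ρ_jl p(y_l | μ_jl, σ²_jl) + (1 − ρ_jl) q(y_l | μ̄_l, σ̄²_l) ].

Estimation is fully Bayesian with conjugate priors — Dirichlet(1) on α,
Beta(1, 1) on each ρ_jl, Normal-Inverse-Gamma(μ0 = data mean, κ0 = 0.01,
a0 = b0 = 0.5) on all Gaussian parameters — via a Gibbs sampler that
alternates component labels (relevance marginalized), per-observation
relevance indicators, and parameter updates. Defaults: 5000 iterations,
1000 burn-in, seeded; model choice by BIC computed from the maximum
posterior log-likelihood.

Numerical choices that matter:

- **Multimodality.** Mixture posteriors are multimodal; `gibbs_fit` runs 3
  chains (k-means initialization, saliency initialized at 0.9) and keeps
  the chain with the highest posterior log-likelihood, recording all
  chains' maxima as a dispersion diagnostic.
- **Label switching** is undone per kept draw by Hungarian matching on
  responsibility overlap with a reference draw. Matching on component
  means is *not* robust here: for low-saliency features the component mean
  is prior-diffuse and essentially noise.
- **An identifiability caveat.** If two components share a coordinate in a
  relevant feature, an alternative parse — one merged component whose
  feature is absorbed by the background density — can reach comparable or
  higher likelihood. The packaged planted-data simulator
  (`simulate_saliency_data`) therefore separates all components in every
  relevant feature; on such data label agreement after alignment
  exceeds 0.9 in essentially all fits. On real norm scores the model is
  used only as an initial exploration; the latent transition model owns
  the final grouping.

## Latent transition analysis

A two-wave latent Markov model on the two scores: classes have diagonal
Gaussian profiles **shared across waves** (measurement invariance, so a
class means the same thing at both time points), initial distribution π
and transition matrix τ. EM with 20 seeded restarts by default,
convergence at log-likelihood gain < 1e-8 (max 500 iterations), variance
floor 1e-6 with a warning when hit, BIC = −2·loglik + p·log N for class
selection. Classification certainty is the relative-entropy statistic
1 − Σᵢₖ pᵢₖ log pᵢₖ/(N log K), averaged over the two waves (1 when K = 1).
Covariates are deliberately excluded from the LTA itself; profiling is a
separate stage.

Classes are labeled by nearest archetype on the (descriptive, injunctive)
mean profile: (1, 0) → descriptive-favorable, (0, 0) → both-against,
(0.5, 1) → injunctive-favorable (the injunctive-favorable archetype is
agnostic about the descriptive score). The favorable/against *side*
dichotomy (favorable = either favorable label) drives the transition
categories, the STERGM homophily term and all influence descriptives.
Downstream analyses use modal assignments; posteriors are retained.

## Covariate profiling

Baseline-category multinomial logit (reference outcome: the both-against
group) fitted by Newton-Raphson with step-halving (log-likelihood
non-decreasing by construction), Wald standard errors from the observed
information, odds ratios with 95% CIs. Categorical covariates expand
against explicit reference levels; continuous scales enter standardized
(coefficients per one s.d.). Complete separation — expected for near-empty
cells such as the smallest group crossed with rare covariate levels — is
*reported* (flagged coefficient, no CI) rather than penalized; a ridge
stabilizer exists but is off by default. School is not a covariate by
default and there is no multilevel term.

## Network change

Per-wave summaries: mean in-degree = ties/nodes (equal to mean out-degree;
displayed to 1 d.p.) and density = ties/(n(n−1)) (2 d.p.). The Jaccard
tie-change index J = A11/(A01 + A11 + A10) is computed over **ordered**
pairs (the networks are directed nominations) on the roster shared by both
waves (intersection policy; a union policy that counts leavers'/joiners'
ties as dissolved/formed is available). The gradual-change band [0.3, 0.6]
is closed at both ends — the boundary convention is ours, the source
guidance saying only "between".

## STERGM

Between waves, tie formation and dissolution are separable
exponential-family processes conditional on the earlier network y⁰:
the formation network y⁺ = y⁰ ∪ y¹ ranges over supersets of y⁰, the
dissolution network y⁻ = y⁰ ∩ y¹ over subsets. Statistics: edges, mutual
(reciprocity), transitive ties (ties i→j with at least one two-path
i→k→j — chosen over raw triple counts as the better-behaved operational
form of "friends of friends are friends"; the alternative is configurable),
and same-side norm-group match (baseline side for formation, follow-up
side for dissolution). Dissolution coefficients parameterize
*persistence*: positive values mean ties survive longer.

Estimation is maximum pseudolikelihood: logistic regression of each
eligible dyad's state on its change statistics, evaluated in the observed
phase network. MPLE coincides with the exact MLE for dyad-independent
specifications (verified against an independent logistic implementation);
for dyad-dependent terms (mutual, transitive) the coefficients are
consistent in practice but the Wald p-values are approximate — the
simulate-then-estimate suite quantifies the bias (≤ 0.1 at the scales
used). Terms that separate or fail to converge are reported as N/A. A
Metropolis-within-Gibbs simulator over each phase's dyad space closes the
loop for calibration tests; with the transitive term it uses an O(n)
per-toggle update and is intended for small-to-moderate networks.

## Influence descriptives

"Friends" are **out-neighbors** (nominations made). Ties partition into
persisting / new / dropped; egos fall into four transition categories from
their favorable/against sides at the two waves. Friend-composition
profiles average **per ego** (each ego contributes one normalized
distribution; a tie-pooled variant is behind a flag). The network-threshold
table compares, across ego categories, the mean baseline share of
favorable-side out-neighbors (zero-out-degree egos excluded and counted).
The intervention test is an uncorrected Pearson chi-square (df = 1) on the
2 × 2 table of {changed to against vs not, among egos on the favorable side
at baseline} × {peer-led, teacher-led}; a warning is attached when an
expected cell falls below 1.

## The synthetic cohort

The generator plants exactly the effects the pipeline must detect, at the
scale of the emulated study: 12 schools (6 per setting, interventions
balanced 3/3 within setting) of 77–177 students, ≤ 10 nominations, target
mean in-degree 6.5, three norm groups at prevalence (0.114, 0.862, 0.024)
with mean (descriptive, injunctive) scores (0.55, 0.15), (0.12, 0.10),
(0.30, 0.62).

- **Ties.** Both directed ties of each unordered pair are drawn jointly
  from P(x, y) ∝ exp(b(x+y) + h·same·(x+y) + m·x·y) with homophily bonus
  h (default 0.15 — weak, matching a setting where norm homophily is
  hard to detect), mutuality bonus m = 2.0, and base rate b calibrated by
  root-finding so the expected mean out-degree hits the target; out-degree
  is then truncated to the cap by random removal.
- **Wave 2.** Each baseline tie survives with probability
  `tie_persistence` (default 0.62, putting the Jaccard index in the
  gradual-change band), with reciprocated baseline ties surviving longer
  (`dissolution_reciprocity` log-odds bonus, centered so the mean
  persistence stays at `tie_persistence`); new ties are drawn from the
  same dyad model — preferentially reciprocating kept ties
  (`formation_reciprocity` odds boost) — at a rate calibrated to keep the
  expected tie count stable. These two knobs plant the reciprocity signal
  the formation and dissolution models are meant to detect.
- **Transitions.** The follow-up side is logistic: base log-odds from
  side persistence (favorable stays favorable with p = 0.60; against
  becomes favorable with p = 0.05), plus `influence_strength` (default
  0.5) per favorable baseline out-neighbor, minus `intervention_effect`
  (default 0.6) in peer-led schools. Influence acts on the binary
  favorable/against dichotomy, matching how transitions are analyzed.
- **Items.** Standardized item values are the group mean plus a
  per-student trait deviation (s.d. 0.05, shared within a wave — this is
  what gives items of a scale realistic positive correlation) plus
  independent per-item noise (s.d. 0.1), truncated to [0, 1], mapped to
  the raw Likert range and rounded to integer steps.
- **Seeds.** One master seed; per-school streams derived through
  `numpy.random.SeedSequence.spawn`, so any school regenerates
  independently of the others.
- **Missingness.** `inject_missingness` blanks all norm items of a random
  student fraction at one random wave each, exercising the complete-case
  path.

What the generator does **not** emulate: roster churn between waves (the
same students appear at both waves; the alignment policies exist for real
data), the peer-supporter nomination process (a random 18% flag in
peer-led schools), within-scale item difficulty differences, ordinal
response styles, and any dependence of missingness on covariates
(missingness is completely at random). Passing recovery tests on this
cohort therefore shows the estimators are correct and calibrated under the
planted mechanism — not that real friendship data satisfies that
mechanism.

## Problem sizes in the shipped checks

The test and acceptance suites use the smallest scales at which each check
is informative: 20 replicates of n = 600 for saliency-mixture recovery,
20 replicates of n = 2000 for LTA recovery (10 in the acceptance script),
50-node networks and 20 replicates for the STERGM loop, 1000 null
replicates of a 4-school cohort for the chi-square type-I rate (500 in the
acceptance script), and a full 12-school pipeline run twice for
byte-identical determinism. All randomness flows from explicit seeds.
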