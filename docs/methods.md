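# Methods

## Unit of analysis and coding

A personal network is one ego, its nominated alters, and the undirected,
unweighted alter–alter ties the ego reports.  The ego is excluded from
the alter–alter graph throughout: by construction the ego touches every
alter, so including it would saturate density and centralization and
push every alter's betweenness toward zero.  Alter identifiers are
scoped per ego; the same person nominated by two egos is two records.

Attributes are recoded to the conventions common in this literature:
sex 0/1 (male/female), education 0/1 (university degree), employment 0/1
(employed; retired counts as unemployed), marital 0/1 (in a
relationship, married included), age in years (≥ 18).  Smoking is asked
on five levels (smoker, occasional, former, non-smoker, never) and
collapsed to three analysis categories — smoker (regular + occasional),
former, non-smoker (non + never) — each of which is dichotomized into a
0/1 outcome; the three indicators of an observed status always sum to 1.
Missing values are carried as an explicit `NA` sentinel, never as zero.

## Structural metrics

On the alter–alter graph with isolates retained: density
|ties|/(n(n−1)/2); connected components (isolates each count); Freeman
degree centralization Σᵢ(d_max − dᵢ)/((n−1)(n−2)).  Per alter: degree
normalized by n−1 and shortest-path betweenness normalized by
(n−1)(n−2)/2 pairs (delegated to networkx).  Networks too small for a
measure (n < 2 for density, n < 3 for centralization) return 0 with a
logged warning rather than erroring, so descriptive tables never abort.
"Standardized" centralities in descriptive output mean this unit-range
normalization; *model* input is additionally z-scored (below).

## The leave-one-out assortativity score

For alter k and category c: (share of k's neighbours with status c) −
(share of the other n−1 alters with status c).  The focal alter is
removed from the network share, matching the statistic's published
worked example (8/24 = 0.33); the ego's own status never enters.
Isolates have no defined score and are dropped from model fitting.
Alters with missing status are excluded from both numerator and
denominator of each share (complete-case within the statistic) — the
≥ 20-complete-alter filter makes this nearly moot, but partial
missingness must be defined.  With complete data the three category
scores of one alter sum to zero (partition identity), which the suite
checks numerically.

## Multilevel model and estimation

Alters (level 1) nested in egos (level 2); random intercept per ego.
The marginal likelihood integrates each ego's Bernoulli product against
N(0, σ²_u) and is evaluated by adaptive Gauss–Hermite quadrature: per
ego, a vectorized Newton step finds the mode of the joint log-density in
u and its curvature; the Hermite rule is applied after re-centring and
re-scaling there; log-sum-exp keeps it stable.  Node count default 15
(one node = Laplace); the suite checks 7/15/25-node agreement to < 1e−4
and 15-node agreement with dense trapezoid integration to < 1e−6.

Optimization is quasi-Newton (L-BFGS-B) on (β, log σ_u) jointly from the
fixed start β = 0, σ_u = 1, with tolerances tight enough that the
relative log-likelihood change is below 1e−9 at convergence.  σ_u is
parametrized on the log scale so the σ_u → 0 boundary stays reachable
without constraints; a boundary estimate is reported as variance 0.
Standard errors come from the numerically differentiated observed
information; at a variance boundary the β block is inverted alone.
Confidence intervals are Wald, exp(β̂ ± 1.96·se); p-values are Wald z
tests with no multiple-testing correction.  A coefficient exceeding 12
in absolute value triggers a complete-separation error naming the term.
Non-convergence returns the fit flagged, with optimizer diagnostics.

Fit statistics: deviance = −2·logLik; AIC = deviance + 2k and
BIC = deviance + k·ln(n_obs) with k = fixed effects + 1 for σ_u;
ICC = σ²_u/(σ²_u + π²/3) using the latent logistic residual variance
π²/3, the standard choice for binary multilevel models; marginal R² =
var(Xβ̂)/(var(Xβ̂) + σ²_u + π²/3) and conditional R² adds σ²_u to the
numerator — so an intercept-only model has marginal R² exactly 0 and
conditional R² equal to the ICC.

The robustness GLMs (statsmodels, binomial family) drop the random
intercept and instead include the ego-level leave-one-out composition
share of the outcome category.  On data simulated with σ_u = 0 the two
routes agree within joint standard errors, which the suite verifies.

## Pipeline

Networks are retained only if at least 20 alters have observed smoking
status (configurable).  The model matrix applies listwise deletion over
all modelled columns plus undefined-assortativity exclusion; every input
alter lands exactly once in the matrix or the exclusion log, with a
reason.  Pooled z-scoring (one scale per fixed effect) is applied on the
retained rows: alter age over all alters, ego age over distinct egos,
normalized degree and betweenness over all alters.  Density, component
count, centralization and the assortativity scores enter models on their
natural scales.

The tie-type × ego-status indicators ("family member smoker" etc.) are
implemented as: alter's tie type is T *and* the ego's three-category
status equals the outcome's category, reference "other" — reading the
ego as the alter's family member / friend.  An alternative
network-composition reading (alter has ≥ 1 neighbour of tie type T in
the category) is exposed via `interaction_mode="network_composition"`;
the published wording does not settle which construction the original
analysis used, so the choice is a configuration switch rather than a
claim.  Each outcome's network block carries two assortativity scores
(smoker plus the outcome's own; former stands in as the second score for
the smoker outcome), matching the published table layout.

The battery is M0/M1/M2/M3 per outcome; individual fit failures are
recorded and do not abort the run.  Nested-model deviance ordering
(M0 ≥ M1 ≥ M3, M0 ≥ M2 ≥ M3) is asserted in tests.

## Synthetic generator

Defaults emulate the study conditions: 76 egos; alters/ego uniform on
20–25; ego smoking 26.3/31.6/42.1% and alter smoking 27.1/11.3/61.6%
(smoker/former/non-smoker); ego age N(54, 16.1²), alter age N(52, 16.1²)
truncated to [18, 95]; sex, education (with a 3.5% alter missing share),
employment, marital and weekly-meeting marginals as in the study's
descriptive table; tie-type mix ≈ 0.49/0.21/0.21/0.09
family/close/simple/acquaintance.

Structure is a planted partition: clusters per ego 1 + Poisson(1.5),
within-cluster tie probability p_in = 0.55, between-cluster p_out =
0.02.  These defaults land mean density ≈ 0.29 and median components
1–2 against the study's 0.3 and 2.  Mean degree centralization comes out
lower (≈ 0.19 vs 0.4) because planted partitions are degree-homogeneous
within clusters; matching centralization would need hub wiring that the
study conditions do not otherwise constrain, and it is left as a known
gap rather than a tuned feature.

Homophily is planted at the cluster level, not by edge rewiring: each
cluster gets a modal status (the family cluster's is tilted toward the
ego's own status with strength h), and each member copies its cluster's
modal status with probability h, drawing from the marginal prevalence
otherwise.  h = 0 decouples status from structure (mean planted-category
assortativity ≈ 0); h = 1 with p_out = 0 yields status-homogeneous
components; the response is monotone in h.  The default h = 0.3 was
chosen once as the value whose implied assortativity spread is of the
order of the study's reported score standard deviations (0.14–0.22).
Ego-effect odds ratios (family-member smoker 2.5, female 0.6) are
injected through a mean-centred logistic tilt of the smoker category;
centring preserves the marginal prevalences while leaving the planted
odds ratios intact.

For parameter recovery the generator has a two-stage mode: statuses are
planted first, each alter's smoker-assortativity is computed from them,
and a fresh binary outcome is drawn from b0 + b1·assort + u_ego with
b1 = ln 3, u_ego ~ N(0, 0.7²) and b0 = −1 (prevalence and ICC of the
order the study reports).  This makes the refitted model correctly
specified — the only coherent way to "plant" an effect of a statistic
that is itself a function of the statuses.

What the generator does **not** emulate: joint covariate distributions
(age × smoking, sex × tie type), link-tracing recruitment, overlapping
alters across egos, or degree-heterogeneous hubs.  Passing tests
therefore demonstrate correctness of the statistics and estimator and
sensitivity to planted signal, not that real field data would yield any
particular coefficient.

## Problem sizes and seeds

Monte-Carlo checks use: 30 seeds × 200 egos for coefficient recovery
(mean within 2 MC SEs of ln 3); 50 default populations for the h = 0
null; 20 default populations for structural calibration; exhaustive
random graphs ≤ 12 alters against brute-force oracles for components and
assortativity; graphs ≤ 8 alters for path-enumeration betweenness.  All
randomness flows through `numpy.random.default_rng` seeded explicitly;
identical (config, seed) reproduce populations bit-for-bit.

## Known limitations

Wald (not profile) intervals; no random slopes, crossed effects or
Bayesian estimation; undirected, unweighted ties only; no record linkage
of alters shared between egos.  The original study's coefficient tables
cannot be reproduced without its deposited data; the pipeline accepts
such data in the package's tabular format should it be obtained.
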