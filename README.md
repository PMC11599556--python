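# egosmoke

Personal-network (egocentric) analysis of adult smoking: structural
metrics of ego networks, a per-alter leave-one-out assortativity
statistic, and two-level random-intercept logistic models predicting the
smoking status of network members.

## The problem

In a personal-network design, each respondent (*ego*) nominates their
social contacts (*alters*), reports each alter's attributes and smoking
status, and says which alters know each other.  The resulting data are
one star-plus-periphery graph per respondent, with alters (level 1)
nested inside egos (level 2).  The scientific question is whether an
alter's smoking behaviour tracks the smoking of their immediate circle —
peer clustering of smoking — over and above individual attributes and
network position.

The package provides the full analysis chain for such data, plus a
synthetic generator that emulates a field study of 76 rural ego networks
(about 22–25 alters each) so the pipeline can be exercised, calibrated
and power-checked without access to the original interviews.

## The statistics at the core

**Leave-one-out assortativity.**  For alter *k* in an ego network of *n*
alters and a dichotomized status category (smoker, former smoker,
non-smoker):

    a_k = (share of k's neighbours in the category)
        − (share of the other n−1 alters in the category)

`a_k ∈ [−1, 1]`; it is undefined for isolates.  Example: 25 alters, 9
smokers, focal smoker with 4 all-smoker neighbours ⇒ 1.00 − 8/24 = 0.67.

**Structural metrics** of the alter–alter graph (ego excluded, isolates
kept): density, component count, Freeman degree centralization
Σᵢ(d_max − dᵢ)/((n−1)(n−2)), normalized degree dᵢ/(n−1) and pair-normalized
betweenness.

**Two-level random-intercept logistic model.**  For the binary status
y_ij of alter i in ego j,

    y_ij | u_j ~ Bernoulli( logit⁻¹( x_ij'β + u_j ) ),   u_j ~ N(0, σ²_u)

fitted by maximum marginal likelihood with adaptive Gauss–Hermite
quadrature (15 nodes by default; 1 node = Laplace).  Reported per fit:
odds ratios with 95% Wald CIs and p-values, σ²_u, the latent-scale
ICC = σ²_u/(σ²_u + π²/3), AIC/BIC/deviance (k = fixed effects + 1), and
latent-scale marginal/conditional R².  The four-model battery (M0
intercept; M1 individual attributes incl. tie-type × ego-status
indicators; M2 network characteristics incl. the assortativity scores;
M3 both) is run per outcome category.  Plain logistic GLMs with an
ego-level leave-one-out composition covariate serve as robustness models.

## Worked example

```sh
python examples/01_worked_example_assortativity.py
```

prints

```
smoker share among a00's neighbours : 1.00
smoker share among the other alters : 0.33
assortativity score for a00         : 0.67
```

— alter a00's immediate circle is entirely smokers while only a third of
the rest of the ego network smokes; the difference, 0.67, is the
assortativity score that enters the regression models.

`examples/02_generate_population.py` draws the default 76-ego synthetic
population and prints its descriptive profile (alter smoking
26.8/12.5/60.7% for a configured 27.1/11.3/61.6%, mean density
0.30 (0.16)); `examples/04_multilevel_models.py` runs the model battery
on data with planted homophily 0.5 and shows the smoker-assortativity
odds ratio in the full model at 8.64 (95% CI 4.21–17.75) — the planted
clustering is detected — and `examples/05_parameter_recovery.py` refits
a known assortativity effect (truth ln 3 ≈ 1.099; mean estimate over five
small populations 1.165).

A thin CLI wraps the same steps:

```sh
egosmoke simulate --out pop --seed 1
egosmoke metrics --in pop --out tables
egosmoke assort --in pop --out tables
egosmoke fit --in pop --model M3 --outcome smoker --nodes 15
egosmoke report --in pop
```

## Data layout

Three UTF-8 delimiter-separated tables with missing sentinel `NA`:
`ego.csv` (one row per ego), `alter.csv` (ego_id, alter_id, attributes,
tie type, meeting frequency) and `tie.csv` (ego_id, source, target —
undirected alter–alter ties).  `read_networks`/`write_networks`
round-trip these losslessly; per-ego GraphML export is available for
visualization.

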