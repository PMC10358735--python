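# Methods

`shortform` implements a complete short-form derivation study for ordinal
questionnaire scales: a generative model of two-wave, two-group Likert data
with known truth; ordinal confirmatory factor analysis; reliability and
measurement-invariance machinery; ant-colony item selection against multiple
psychometric criteria; and regularized partial-correlation networks. This
note records the models, the defaults and why they were chosen, the
numerical decisions, and the limits of what the synthetic studies show.

## The generative model

Ordinal items are discretizations of standard-normal latent responses

    y*_i = lambda_i' eta + eps_i,     X_i = sum_c 1(y*_i > tau_ic),

with standardized loadings, factor correlation matrix `Phi`, unique variance
`1 - communality`, and four ordered thresholds per item (five categories,
codes 0-4). The default instrument mirrors a 14-item perceived-stress scale:
seven items load a *helplessness* factor, seven a *self-efficacy* factor,
the factors correlate -0.37, and self-efficacy items are reverse-keyed in
the stress-keyed total. An optional general factor (orthogonal to the
specifics) turns the truth into a bifactor structure.

**Thresholds.** Default cut-points are symmetric (-1.2, -0.4, 0.4, 1.2) with
a per-item shift spread linearly over 0-0.6, producing item skewness of
roughly 0-0.5 and mild kurtosis — ordinal data that are visibly non-normal
but not pathologically so, matching the regime the screening rules
(|skewness| or |excess kurtosis| > 1.5 plus a significant Shapiro-Wilk test)
are designed for.

**Retest.** Wave-2 factor scores follow a latent first-order autoregression,
`eta_2 = s * eta_1 + sqrt(1 - s^2) * zeta`, with per-factor stability
`s = 0.85` by default and fresh unique noise at wave 2. With 2-item sums and
loadings around 0.90 this implies a retest ICC near 0.72-0.74 (closed form
below), i.e. "good" test-retest reliability with some headroom over the 0.70
cut-off.

**Groups.** A binary split (defaults 53% / 47%) with optional additive
offsets on chosen loadings or thresholds in the second group injects
measurement non-invariance with a known location.

**Covariates, in closed form.** Every implied moment of the ordinal codes is
available without simulation: the covariance of two codes is a
bivariate-normal rectangle sum evaluated by Gauss-Legendre quadrature, and
the covariance of a code with its latent response is the attenuation slope
`a_i = sum_c phi(tau_ic)`. A covariate `C = w' eta + sigma e` is calibrated
so that its model-implied correlation with the stress-keyed total equals the
target exactly: with `c_p = sum_i s_i a_i (Lambda Phi)_ip` and
`Q = c' Phi^-1 c`, the canonical direction `w = k Phi^-1 c` with
`k = r_target * sd(total) / Q` and `sigma^2 = 1 - k^2 Q` achieves it
(observed correlations land within sampling error of the target; the
generator's verification report demonstrates |deviation| < 0.01 at
n = 100,000). Default targets are +0.59 for mental-health problems, -0.53
for stressor recovery ability and -0.44 for a self-efficacy covariate,
relative to the stress-keyed total. The self-efficacy sign is a package
convention: a stress total that correlates -0.53 with recovery ability
cannot plausibly correlate +0.44 with self-efficacy, so the magnitude is
kept and the sign made consistent.

**What the generator does not emulate.** No panel attrition, response
styles, careless responding, response-time artifacts, or missingness beyond
MCAR (default rate 0.001). Passing tests therefore demonstrate correctness
of the estimators and the selection machinery under a well-specified ordinal
factor model — not robustness to the messiness of real survey data.

## Ordinal CFA

Polychoric correlations are estimated pairwise in two steps: thresholds from
inverse-normal cumulative proportions, then the latent correlation by
maximizing the bivariate-normal two-way-table likelihood (coarse grid scan
refined by bounded Brent, tolerance 1e-6, estimates clipped to +-0.999).
Rectangle probabilities use a 24-node Gauss-Legendre quadrature of the
conditional decomposition, accurate to ~1e-10. Asymptotic variances come
from the numerical observed information and feed the DWLS weights.

The DWLS discrepancy is `F = sum_{i<j} (s_ij - sigma_ij(theta))^2 / avar_ij`
over the unique off-diagonal polychoric correlations; the reported statistic
is the *unadjusted* `T = F` (weights already carry the 1/n scale). No
mean-and-variance adjustment is applied, and the estimator tag says so: the
unadjusted statistic is known to be conservative (in our null simulations it
runs well below its degrees of freedom), which is why inferential decisions
in the invariance ladder default to the ML path (below). The ML path fits
the normal-theory discrepancy to the Pearson matrix with free uniquenesses,
`T = (n-1) F_ML`.

Identification fixes all factor variances to 1. Bifactor models make the
specific factors orthogonal to the general factor and to each other (the
standard convention). The CFI baseline is the independence model;
`CFI = 1 - max(T - df, 0) / max(T_B - df_B, T - df, 0)` and
`RMSEA = sqrt(max(T - df, 0) / (df (n-1)))`, with RMSEA reported as 0 for
saturated models. Optimization is L-BFGS-B on an unconstrained
reparameterization (correlations through tanh, variances through log),
tolerance 1e-12 on the objective, 500 iterations; Heywood cases are flagged,
never clipped. Non-convergence returns a flagged result rather than raising,
because the ant-colony loop must treat it as a penalized candidate.

## Reliability

Cronbach's alpha is the classical variance ratio on listwise-complete rows.
McDonald's omega is `(sum lambda)^2 / ((sum lambda)^2 + sum theta)` from a
scale's own one-factor solution; a 2-item scale is under-identified, so the
tau-equivalent solution `lambda = sqrt(r_polychoric)` is used (negative
inter-item correlation yields omega 0). The retest ICC defaults to the
two-way random-effects, absolute-agreement, single-measurement coefficient
ICC(2,1) computed from the ANOVA mean squares with k = 2 occasions —
absolute agreement is the stricter and more common test-retest choice — with
ICC(3,1) consistency available; the implementation is checked against
`pingouin.intraclass_corr` in the test suite.

## Ant-colony item selection

Candidate subsets (k items per factor, default 2) are scored on five
criteria: CFI (cut-off 0.96) and RMSEA (0.05) of the subset's two-factor
DWLS CFA, the worse factor's omega (0.85), the worse factor's retest ICC on
sum scores (0.70), and the mean absolute deviation of the stress-keyed
total's covariate correlations from their targets (0.15). Each raw value
maps to a pheromone through a logistic centered at its cut-off,
`phi = 1 / (1 + exp(-(x - cutoff)/scale))` with the sign flipped for
lower-is-better criteria; the scale defaults to half of 10% of the cut-off
(half the stated tolerance, 0.075, for the covariate criterion). The mapping
is smooth, bounded, equals 0.5 exactly at each cut-off, and its equal-weight
sum `Phi = sum_c phi_c` is monotone in every criterion.

Ants draw k distinct items per factor sequentially with probability
proportional to per-item pheromone. After each iteration pheromone decays by
the retention multiplier 0.70 ("evaporation rate" read as retention, the
convention of the scale-shortening literature; the alternative reading is a
config switch) and the global-best solution deposits its `Phi` on its items
(elitist scheme; iteration-best deposits available as an option). Defaults:
40 ants, 30 iterations, 5 independently seeded runs, early stop after 10
unchanged iterations, pheromone floor 0.01 to prevent absorbing states. The
modal best item set across runs is reported with its consistency count.
Because the 2-per-factor candidate space is small (C(7,2)^2 = 441), an
exhaustive enumerator provides the optimality oracle, and all evaluations
are cached per data bundle, so the five runs and the enumeration share work.

Covariate correlations use sum scores (not factor scores), and the omega and
ICC criteria take the worse of the two factors, since a single cut-off must
bind both subscales.

## Measurement invariance

The multigroup ladder runs configural -> metric (equal loadings) -> scalar
(equal thresholds / intercepts) -> strict (equal residuals), comparing
adjacent levels by chi-square difference at alpha = 0.05. Identification
follows a delta-parameterization analogue: group 1 sets the scale (unit
latent-response variances, zero latent means, unit factor variances); other
groups gain free factor (co)variances at metric and free latent means plus
free item scales at scalar. Thresholds (and saturated means on the ML path)
are profiled out analytically, which keeps the optimization dimension small
enough for replicated simulation studies. Degrees of freedom are counted as
statistics minus free parameters, profiled parameters included.

**Estimator choice is a calibration result.** Under full invariance (200
replicate null datasets, n = 1,437, two groups) the ML likelihood-ratio
difference test is well calibrated — non-rejection 96-97% at alpha = 0.05
and approximately uniform p-values on both the metric and scalar steps —
while the naive DWLS difference is strongly conservative (mean p ~ 0.70).
The ladder therefore defaults to the ML path for decisions; the DWLS ladder
remains available with its documented caveat. Power: a single loading
lowered by 0.25 in one group is detected on the metric step with ~82% power
at n = 1,437 with 3-indicator factors; 2-item factors carry much less
loading information (~42%).

One propriety caveat, standard in ordinal invariance testing: freeing the
group-2 item scales when thresholds are constrained means the scalar model
is not strictly nested in the metric model's moment space; the difference is
floored at zero, matching field practice.

The greedy partial-invariance search frees, one at a time, the constrained
parameter whose release drops chi-square the most, re-testing after each
release, up to 4 releases by default. On planted single-parameter
violations it frees exactly the planted parameter first.

## Partial-correlation networks

Node scores are nonparanormal-transformed (ranks -> r/(n+1) ECDF -> normal
quantiles, standardized). The graphical lasso (scikit-learn's solver) runs
along a 100-point log-spaced penalty path from `lambda_max` (empty graph)
down to `0.01 lambda_max`; EBIC with gamma = 0.25 selects the penalty. The
EBIC likelihood term is evaluated at the unpenalized Gaussian MLE restricted
to each candidate support (computed by projected gradient ascent on the
concave log-likelihood): this reads EBIC as a support-selection criterion
and prevents the penalty from being traded against shrinkage bias, which
otherwise retains spurious near-zero edges at large n. Reported edge weights
are the regularized partial correlations
`w_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)` from the selected glasso fit.

Centralities: strength `sum_j |w_ij|`; closeness and betweenness on
distances `1/|w|` (networkx shortest paths). On disconnected graphs,
unreachable nodes simply contribute nothing to closeness and isolated nodes
score zero — the paper-silent case, documented here. Edge robustness uses
nonparametric case resampling with full re-estimation (including penalty
re-selection) per draw and percentile 95% intervals; centrality stability
uses case-drop subsampling and the CS coefficient (largest drop proportion
at which subsampled centralities correlate >= 0.7 with the full-sample
values in >= 95% of subsamples).

## Problem sizes and numerical defaults

Simulation studies in the test suite use the study-scale n = 1,437 where the
claim concerns that design (selection criteria, run consistency, type-I
calibration: 200 replicates; oracle equivalence: 20 bundles), and larger
single checks (n = 50,000-100,000) for moment-convergence oracles. The
pipeline's bootstrap default is 1,000 draws; smoke tests use the 100-draw
floor. Master seeding uses `numpy.random.SeedSequence` spawning so every
stage has an independent, reproducible stream; identical config and seed
reproduce byte-identical reports.

## Known limitations

- The DWLS test statistic is unadjusted; its absolute fit indices are usable
  (CFI/RMSEA behave sensibly) but its chi-square is conservative and its
  naive difference test should not be used for invariance decisions.
- Polychoric estimation is pairwise (no joint positive-definiteness
  enforcement); a ridge fix-up with a log entry guards the network path.
- Partial scalar release on the ML path profiles shared intercepts with the
  freed items' residuals zeroed, a slight approximation to the exact profile.
- Omega for 2-item scales assumes tau-equivalence within the pair.
- No exploratory factor analysis, second-order models, longitudinal
  invariance, multiple imputation, or IRT scoring.
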