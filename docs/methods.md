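# Methods

## The generative model

All downstream stages are exercised on a synthetic cohort whose joint
statistical structure matches the study design the package implements: 68
participants in three age cohorts (n = 28, ages 18–39, M = 28.04, SD = 5.27;
n = 20, 40–59, M = 48.75, SD = 5.80; n = 20, 60–78, M = 69.15, SD = 4.61),
ages drawn per cohort from truncated normals (only cohort n/M/SD/range are
specified, so the truncated normal is the maximum-entropy-style reading).

With `z` the within-sample standardized age, the latent structure is

```
g  = ρ_ag·z + √(1−ρ_ag²)·ε                 fluid cognition, ρ_ag = −0.859
w  = α·z + β·(−g) + γ·e                     WMH exposure, var(w) = 1
f_d = a_d·g + √(1−a_d²)·u_d                 domain factors, d ∈ {EF, PS, M}
```

`(α, β)` solve the 2×2 linear system given by the targets
corr(z, w) = 0.68 and corr(g, w) = −0.68; `γ` normalises var(w) = 1. The
construction is rejected (never clipped) when the targets imply a
non-positive-definite latent covariance. Domain loadings come from the triad
identities `a_i·a_j = r_ij` applied to the pairwise domain correlations
(0.846, 0.604, 0.557); at the defaults a_EF ≈ 0.958, a_PS ≈ 0.883,
a_M ≈ 0.631. Each of the 12 tests is `0.8·f_d + 0.6·noise`, already
oriented so that higher = better. Log global WMH volume (k = 0.7 series) is
`6.11 + 1.40·w` (mm³ after exponentiation); the periventricular, deep, and
k = 0.5 series are correlated-noise copies with targets 0.99, 0.64, 0.99 and
their own printed location/scale. Four tract-level WMH covariates load on
`w` with δ = 0.8; their log-scale locations (uncinate 4.0, forceps major
4.6, cingulate bundle 3.8, anterior thalamic radiations 5.2, SD 1.2)
are package choices ordered so the anterior thalamic radiations carry the
heaviest load. Vocabulary is N(58.53, 4.53²), independent of age; sex is
Bernoulli(0.5).

A note on attenuation: with test loading 0.8, the regression factor score of
a 4-test domain correlates with its latent at R = √(4·0.64 / (1 + 3·0.64)) ≈
0.936, so *estimated* domain-score correlations are attenuated by R² ≈ 0.88
relative to the latent targets (e.g. EF–PS ≈ 0.74); the 12-test general
factor recovers `g` at ≈ 0.92. Tests of estimated scores therefore pin the
closed-form attenuated values; calibration tests address the latents.

## Connectomes

Each subject receives a symmetric 246-node streamline-count matrix (210
cortical nodes in 7 intrinsic networks of 30, 36 subcortical nodes forming
the SUB network; lobe sizes Frontal 70, Temporal 40, Parietal 38, Insular
12, Limbic 14, Occipital 36, Subcortical 36). The group baseline assigns
each node pair an edge-presence probability and log-normal expected count
(σ = 0.75) by edge class:

| class                         | presence | weight × |
|-------------------------------|---------:|---------:|
| cortical within-network       | 0.8      | 2.0      |
| subcortical–subcortical       | 0.7      | 0.5      |
| within-lobe (cross-network)   | 0.5      | 1.5      |
| SUB → DMN/FPN projections     | 0.9      | 1.2      |
| other SUB–cortical            | 0.15     | 0.5      |
| other between-lobe            | 0.3      | 0.8      |

The global count scale is calibrated numerically (Brent root-finding on the
exact Poisson survival function) so the expected post-threshold density is
0.33. The planted signal set is every SUB-SUB edge plus a seeded 50% of the
SUB-DMN and SUB-FPN blocks; a subject with standardized WMH exposure `b` has
expected counts multiplied by `exp(−κ·b)` (κ = 0.6) on signal edges.
Observed counts are independent Poisson draws, symmetrized, with cells below
3 streamlines zeroed (the streamline threshold).

Two structural facts motivated the class table, and were fixed before the
package's statistical tests were written, by first-order analysis of the two
metrics they control. (1) Newman's Q rises with WMH exposure only if the
between-module (SUB–cortical) share of the planted signal outweighs the
within-module (SUB-SUB) share relative to the graph's within-module weight
fraction — hence strong cortical within-network structure and enriched SUB
projections. (2) Strength-normalized communicability is governed by strength
homogeneity (the Perron term of the matrix exponential), so it falls with
age only if subcortical nodes sit *below* the mean node strength and are
pushed further down by WMH loss — hence the low subcortical weight
multipliers. With both in place the generator reproduces the study's sign
pattern (density and communicability negative with age and WMH load,
modularity positive) in ≥ 90% of seeds. The Onnela clustering coefficient
comes out mildly negative with age in this generator, whereas the study
reported a positive age association (and null associations with cognition
and WMH); clustering is not part of the emulated sign pattern.

What the generator does **not** emulate: spatial geometry and distance-
dependent connectivity, tractography biases (gyral bias, SIFT filtering
artifacts), subject-level registration error, non-Poisson overdispersion of
streamline counts, subcortical hub strength (deliberately suppressed, see
above — so ROI-level importance rankings do not concentrate on subcortical
nodes the way edge-level importance does), and any cerebellar structure.
Passing tests therefore demonstrate correctness of the statistical machinery
and recoverability of planted effects, not fidelity of any particular brain
network model.

## Factor scores

Scores on the 12 tests are OLS-residualized on [vocabulary, sex] before
factoring ("controlling for" is read as residualization). The general
factor is the first unrotated factor of the iterated principal-axis
algorithm: communalities start at squared multiple correlations, the reduced
correlation matrix is re-eigendecomposed until the largest communality
change falls below 1e−6 (Heywood communalities are clipped to 1−1e−6 with a
warning; non-convergence at 100 iterations is an error reporting the last
change). Factor scores use the regression (Thurstone) method, standardized;
Bartlett scoring is available. The factor sign is fixed by requiring a
non-negative loading on the first test, which makes corr(age, fluid score)
negative under the generator defaults.

## Associations

WMH volumes are natural-log transformed before every analysis (the base
only rescales, leaving correlations unchanged). Partial correlations are
Pearson correlations of OLS residuals with t-based p-values on n − 2 − c
degrees of freedom (Fisher convention; the source convention is not
stated). BH-FDR is applied strictly within declared families — one family
per analysis table — and every correlation row carries its family id.
Power uses the Fisher-z approximation: with λ = atanh(r)·√(n−3), two-sided
power is Φ(λ − z_c) + Φ(−λ − z_c); this reproduces the study's a-priori
calculation (r = 0.35, n = 68, α = .05 → 0.84).

## PLSR and component selection

`fit_plsr` implements SIMPLS on column-centered X and Y with no variance
scaling (the `plsregress` convention): per component, the dominant right
singular vector of the current cross-product S = X₀'Y₀ gives the X-weight;
scores are normalized; S is deflated by the orthonormalized X-loading
basis. Coefficients are B = R·Q' with an intercept mapping the training
means onto each other. Outcomes are kept on their raw scales by default:
the baseline MSE then equals the sum of the outcome sample variances
(age in years dominates), matching the reference convention; a standardized-
outcome option exists for cross-outcome-comparable importance.

Fivefold CV uses a seeded, unstratified, near-equal random partition. For
each candidate component count 1..A_max the held-out predictions are
assembled across folds; CV-MSEP is the squared error summed over outcomes
and averaged over observations, CV-PCTVAR = 100·(1 − CV-MSEP/baseline), and
ties in the minimiser resolve to the smaller count. Per-outcome performance
is the squared Pearson correlation of assembled held-out predictions with
the observed outcome. Edge importance is the mean over CV folds of |B|
averaged across outcomes; ROI importance sums importances over incident
edges. The study's reported CV-PCTVAR ≈ 98 has no operational definition we
can verify without the original data; the definition above is documented,
not tuned, and both CV-PCTVAR and per-outcome r² are reported.

## Resampling nulls

Each subnetwork model restricts X to one edge mask (SUB-SUB = both
endpoints subcortical, 630 edges; SUB-X = exactly one endpoint subcortical,
other in network X, 1080 edges each; masks pairwise disjoint). Per
iteration: a fresh 80/20 split; inner fivefold CV *on the training set only*
re-selects the component count (selection inside every iteration, per the
stated procedure); performance is the mean over the three outcomes of
Pearson r(y, ŷ) on the test set (the aggregation rule is a package choice;
per-outcome distributions are retained). The null twin repeats the whole
procedure with the outcome *rows* jointly permuted — a fresh permutation per
iteration — preserving the outcome inter-correlations. Effect sizes:
two-sample KS (asymptotic p) and Cohen's d with pooled SD; summaries are
the median and the empirical 2.5/97.5 percentiles (linear interpolation;
the rule moves the bounds only in the third decimal at these sizes).
Default n_iter = 5000; the analysis driver runs 500, which moves the median
by < 0.02.

A Monte-Carlo allocation note: under a no-signal generator the per-cohort
Cohen's d is dominated by the cohort's fixed chance X–Y correlation
(SD ≈ 0.6 at n = 68, mean 0), not by split noise, so null checks average d
over many cohorts with modest n_iter rather than the reverse.

## Graph metrics

The concrete formulations (the source's equations live in an unavailable
supplement; these are the field-standard readings of its verbal
definitions, each swappable behind the metric registry):

* **Density** — fraction of node pairs with nonzero weight.
* **Clustering** — Onnela weighted coefficient on weights normalized by the
  matrix maximum; degree < 2 contributes 0; global value is the node mean.
* **Modularity** — Newman weighted Q with resolution γ. The a-priori
  partition is the 8 atlas networks (7 cortical + SUB); weighted edges are
  used throughout (binarization is a non-recoverable alternative reading).
* **Consensus partitions** — Lancichinetti–Fortunato consensus over seeded
  Louvain runs (igraph's multilevel implementation; default 100 runs,
  co-assignment threshold τ = 0.5, ≤ 20 rounds). If the agreement matrix
  reaches a fixed point while runs still oscillate between equally good
  optima, the tie is broken by the partition with maximal Q on the input
  graph; genuine non-convergence raises an error reporting the residual
  agreement entropy. γ ∈ {1, 1.25, 1.5}.
* **Communicability** — Crofts–Higham strength-normalized form: mean
  off-diagonal of expm(S^(−1/2)·W·S^(−1/2)), isolated nodes excluded; scale
  invariant by construction.

Metric association tables reuse the correlation machinery (one FDR family
per table); the regression table reports unadjusted and adjusted (age +
fluid cognition) OLS of each metric on log global WMH with b, 95% CI,
standardized β, and R².

## Mediation

OLS path models: each mediator on [1, x]; the outcome on [1, x, mediators].
The indirect effect of mediator i is a_i·b_i; under OLS the total effect
decomposes exactly as c = c′ + Σ a_i·b_i. Confidence intervals are
percentile bootstrap over case resamples (default 10 000; the cited
framework's default), fully vectorized; z = point/bootstrap-SE with
two-sided normal p. Coefficients are unstandardized (age in years), with
standardization available. A borderline note: with the calibrated
correlation structure the population partial correlation of log WMH with
the *estimated* fluid factor given age is ≈ −0.19, so at n = 68 the CI
excludes zero in only ~35% of cohorts — the single-cohort significance of
the global indirect effect is intrinsically marginal at this sample size
(the study's own z ≈ 2.0 sits at the same boundary). The qualitative
global-vs-tract contrast is therefore demonstrated at a 4× cohort, where
power for the global effect is ≈ 0.9 while no individual tract among four
sharing one latent is reliably singled out.

## Numerical choices and problem sizes

Seeds are explicit everywhere; one master seed spawns per-stage seeds in
the pipeline, and identical seeds reproduce bit-identical outputs. The
test suite runs the generator-to-inference path at the study's n = 68 with
scaled Monte-Carlo sizes chosen for stable assertions: 200 cohorts for
calibration means, 50 cohorts for importance enrichment, 40 cohorts ×
80 iterations for the null effect-size average, 500 simulations ×
1000 bootstrap draws for mediation coverage, 20 cohorts for the metric sign
pattern, and 10⁵-participant cohorts for closed-form calibration checks
(±0.01).

## Known limitations

Real-data magnitudes (CV-PCTVAR, tabulated effect sizes, metric means)
are not reproducible without the original cohort and are not targeted;
only printed calibration targets, closed-form identities, and qualitative
structure are. The generator's independence assumptions (Poisson edge
noise, independent test noise) make recovery easier than in real data.
ROI-level importance rankings depend on the suppressed subcortical strength
noted above. No nodal metrics, rich-club analysis, serial mediation, or
measurement-invariance testing.
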