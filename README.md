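# wmhnet

Statistical machinery for studying how white-matter hyperintensities (WMH)
relate to age, fluid cognition, and structural brain connectomes in healthy
aging — implemented as a tested, reusable pipeline exercised end-to-end on a
synthetic cohort generator that emulates the study's statistical structure.

WMHs are bright FLAIR-image lesions of cerebral white matter reflecting
cerebrovascular insufficiency. Their volume rises with age and is associated
with slower, less efficient neural communication, particularly through
subcortical-cortical pathways. This package implements the full analysis
chain linking those quantities:

* **Cohort simulation** (`wmhnet.synth`) — a three-cohort sample (younger /
  middle-aged / older, n = 28/20/20), a latent fluid-cognition factor *g*
  with corr(age, g) = −0.859, a log-normal WMH exposure *w* calibrated in
  closed form to corr(age, w) = 0.68 and corr(g, w) = −0.68, a 12-test
  battery in three correlated domains, tract-level WMH covariates, and
  246-node streamline-count connectomes in which WMH burden attenuates
  subcortical-subcortical and subcortical-cortical edges via
  exp(−κ·w).
* **Factor scores** (`wmhnet.factors`) — first unrotated principal-axis
  factor of the battery, controlling for vocabulary and sex; domain scores
  for perceptual speed, executive function, and memory.
* **Associations** (`wmhnet.assoc`) — Pearson and partial correlations on
  log-transformed WMH volumes, Benjamini–Hochberg FDR within explicit
  families, and the Fisher-z power calculation.
* **Whole-brain prediction** (`wmhnet.plsr`) — SIMPLS partial least squares
  regressing the 30 135 vectorized connections on (age, fluid cognition,
  log WMH) jointly; fivefold cross-validated component selection by
  CV-MSEP; edge and ROI importance as cross-validated |β| sums.
* **Subnetwork resampling** (`wmhnet.resampling`) — 80/20 train/test
  resampling of edge-masked models (SUB-SUB and SUB-to-cortical-network),
  permuted-outcome null twins, Kolmogorov–Smirnov and Cohen's *d* effect
  sizes, median and 95% prediction intervals.
* **Network topology** (`wmhnet.graphs`) — density, Onnela weighted
  clustering, Newman modularity Q with resolution γ (a-priori 8-network and
  Louvain consensus partitions), strength-normalized communicability, and
  unadjusted/adjusted regressions of each metric on WMH load.
* **Mediation** (`wmhnet.mediation`) — simple and parallel-mediator
  age → WMH → fluid-cognition models with percentile bootstrap CIs.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort (seed 42) and write tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_factor_scores.py
python analysis/03_correlations.py
python analysis/04_whole_brain_plsr.py
python analysis/05_subnetwork_resampling.py
python analysis/06_network_metrics.py
python analysis/07_mediation.py
```

Selected output (what it means in brackets):

```
sample r(age, latent g)      = -0.901     [age-related fluid decline]
sample r(age, log WMH k=.7)  = +0.718     [WMH volume rises with age]
mean connectome density after streamline threshold = 0.326

fluid factor score: r with age        = -0.840
fluid factor score: r with latent g   = +0.909  [factor recovers the latent]

partial r(global WMH k07, fluid | age) = -0.314 (p = 0.010)
power to detect r = 0.35 at n = 68, two-tailed alpha = .05: 0.84

   name  n_edges  ks_stat  cohens_d  median_true
SUB-FPN     1080     1.00      4.59         0.79
SUB-DMN     1080     0.99      4.48         0.79
SUB-SUB      630     0.99      4.42         0.79   [planted subcortical signal
SUB-VIS     1080     0.47     -1.26        -0.30    separates from the null]

simple model (global WMH): direct effect of age = -0.0389
  indirect via log_wmh_global   -0.0103 [-0.0192, -0.0023] significant
parallel model (4 tracts):
  indirect via uncinate         -0.0035 [-0.0086, +0.0019] n.s.   [global, not
  ...                                                              tract-specific,
                                                                   mediation]
```

Graph metrics reproduce the qualitative direction pattern: density and
communicability fall with age and WMH load while modularity rises
(increasing segregation of the structural network).

The `wmhnet` console command exposes the same stages
(`wmhnet simulate|factors|assoc|plsr|resample|graph|mediate|run`); see
`wmhnet --help`.

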