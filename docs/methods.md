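# Methods

`adherenet` implements a graph-theoretic analysis of resting-state functional
connectomes aimed at one behavioural question: do the organizational patterns
of a person's brain network at baseline predict how well they will adhere to a
subsequent mental-training program (home-practice sessions completed,
instruction classes attended)? The package covers the full chain from
parcellated BOLD time series to classifier evaluation, together with a
synthetic cohort generator that plants the statistical structure the analysis
is designed to detect, so every stage is testable end to end without access to
any MRI data.

## Connectome construction and binarization

Each participant contributes a timepoints × ROI matrix of region-averaged
BOLD-like series (default 145 timepoints × 131 ROIs). The weighted connectome
is the matrix of pairwise Pearson correlations with the diagonal zeroed.
Binarization keeps an edge wherever r > T, for thresholds T on the inclusive
grid 0.05, 0.10, …, 0.50. Three consequences of this rule are deliberate:

* **Signed thresholding.** Negative correlations never create edges at any
  T ≥ 0.05. An absolute-value variant (|r| > T) exists behind
  `RunConfig(absolute_threshold=True)` for sensitivity analyses; every results
  file records which mode produced it. Signed is the default because the
  binarization rule as stated keeps only supra-threshold positive
  correlations.
* **Strict inequality.** Ties at the threshold go to 0, so a matrix whose
  largest off-diagonal r equals T produces an empty graph.
* **Nestedness.** Because a single matrix is thresholded at increasing cutoffs,
  edge sets are nested along the sweep and edge counts are non-increasing —
  asserted as a property test.

No Fisher z-transform and no global-signal regression are applied; parcellated
series are the pipeline's entry point and upstream preprocessing is out of
scope.

## Graph metrics

All metrics operate on the binary graph. For node i with degree K_i and L_i
triangles through it:

* clustering coefficient C_i = 2·L_i / (K_i(K_i − 1)), C_i = 0 for K_i < 2
  (the formula is 0/0 there; zero is the standard convention and keeps means
  defined);
* geodesic distance L_ij = unweighted hop count, ∞ for disconnected pairs;
* global efficiency E_glob = mean over ordered pairs of 1/L_ij with 1/∞ = 0.
  Harsh thresholds fragment the network, and this convention keeps the metric
  defined on every component structure;
* local efficiency Eloc_i = E_glob of the subgraph induced by i's neighbours
  (0 for K_i < 2), mean over nodes reported as E_loc;
* degree centrality D_i = row sum of the adjacency — the hubness measure;
* modularity Q of a partition c: Q = (1/2m)·Σ_ij [A_ij − k_i k_j / 2m]·δ(c_i,c_j).
  Partitions come from the Louvain algorithm run `louvain_reps` times (default
  150) with seeds derived deterministically from the run seed; the mean Q is
  reported and the partitions themselves are discarded. Resolution is fixed at
  1. An edgeless graph gets Q = 0 with a warning rather than an error so that
  sweeps never crash at extreme thresholds. Fragmented graphs are processed
  jointly (standard Louvain behaviour on disconnected graphs).
* binarized system segregation over the five resting-state networks
  (subcortical, sensory, default mode, attention/executive, language/memory):
  z_binw is the realized within-network edge count divided by the possible
  within-network pair count, averaged over the five networks; z_binb is the
  realized between-network edge count divided by the possible between-network
  pair count, pooled over all network pairs; S = (z_binw − z_binb)/z_binw.
  Pooling treats "between networks" as one class; a per-network-pair average is
  available via `RunConfig(pairwise_between=True)`. S is undefined (an error
  from the metric; recorded as missing in sweep tables) when z_binw = 0, and a
  network with fewer than 2 nodes is rejected.

Efficiency sums are computed by simultaneous breadth-first search expressed as
boolean matrix products (reachability by level), which terminates after
diameter-many products and matches a Floyd–Warshall oracle to 1e−10 on random
graphs. Exactness, not approximation: the reformulation only changes the order
of traversal.

## Association scans

Each (metric, scope, threshold) cell is correlated with an adherence score by
Pearson r; significance comes from a two-sided permutation test with the
add-one estimator p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1), n_perm = 1000
by default. The smallest attainable p is exactly 1/(n_perm + 1) = 9.99e−4 and
p = 0 is never reported. Permutations are drawn independently per test from a
seed derived from the scan seed and the test's position; the identity
permutation is not excluded (its probability is negligible and excluding it
would bias the estimator upward). The test is two-sided because both positive
(clustering, local efficiency, segregation) and negative (global efficiency,
several hubs) associations are scientifically expected.

Benjamini–Hochberg FDR (q = 0.05) is applied over these families:

* **nodal scan** — the 131 nodes within one threshold; a node significant at
  ≥ `min_sig_thresholds` thresholds (default 3) enters the robust set. The
  stricter full-range rule is `min_sig_thresholds = 10` on the default grid;
  neither rule is silently preferred — the threshold used is in every results
  file.
* **global scan** — all global metrics × thresholds within one
  (group, outcome); undefined cells (e.g. segregation at a threshold where
  some participant has no within edges) are dropped from the family and
  reported as missing.

Whether FDR should pool across thresholds is genuinely open; per-threshold
families (nodal) and joint metric × threshold families (global) are the
recorded choices, and the run record names them.

## Classification

Participants are labelled high adherence iff homework > 10 (strict; 10 of 20
is low). Features are nodal clustering and degree at the robust nodes, taken
at reference threshold T = 0.35. Round(0.25·n) participants are held out with
stratification. On the training partition only, greedy backward elimination
scored by leave-one-out accuracy of a 100-tree random forest drops the feature
whose removal best preserves accuracy, stopping when every removal would hurt
or a configured minimum remains. Four classifiers (random forest, AdaBoost,
decision tree, Gaussian naive Bayes; library-default hyperparameters, echoed
in the run record) are then scored by LOOCV accuracy once per seed (five
seeds drive classifier-internal randomness; the LOOCV split itself is
deterministic), reported as mean ± 1.96·sd/√k, and the pooled mean over all
4 × 5 = 20 scores is also emitted. Held-out ROC curves use the mean predicted
high-class probability across seeds; AUC is trapezoidal and equals the
normalized Mann–Whitney concordance count (asserted exactly in tests). A
single-class held-out set leaves AUC undefined (reported missing).

Feature selection never sees the held-out set, and the test suite contains a
deliberate leakage variant (selection on all data before LOOCV) demonstrating
that the guard matters: under pure noise it inflates accuracy well above
chance.

## The synthetic cohort generator

The generator emulates the study conditions: 51 participants split 29
(meditation) / 22 (creative writing), 131 ROIs over five networks of sizes
17/30/28/30/26 (subcortical smallest, association systems largest), 145
timepoints. Participant p draws a coupling weight w_p ~ N(w̄, σ_w²) truncated
at 0; ROI i in network s follows

    x_i(t) = w_p·latent_s(t) + g·global(t) + ε_i(t),

with independent standard-normal latent and global series and
ε ~ N(0, noise_sd²). The latent-factor construction guarantees a positive
semidefinite covariance and exposes one scalar knob — w_p — that the analysis
should recover: within-network correlation (w_p² + g²)/(w_p² + g² + σ²) rises
with w_p while between-network correlation g²/(w_p² + g² + σ²) falls, so
participants with high coupling have more segregated connectomes. Homework is
round(clip(a + b·w_p + ε, 0, 20)) with intercept a = 10 − b·w̄ so the expected
mean sits mid-scale; attendance is generated analogously on its 0–4 scale.
Rounding and clipping are intentional: bounded counts with ties are what real
adherence scores look like, and they stress the permutation machinery.

Defaults, with units and rationale:

| parameter | default | why |
|---|---|---|
| coupling_mean w̄ | 1.0 (signal sd units) | sets mean within-network r ≈ 0.56, a realistic resting-state value |
| coupling_sd σ_w | 0.3 | 30% between-subject variability in coupling |
| global_weight g | 0.5 | shared signal giving between-network r ≈ 0.1–0.2 at mean coupling |
| noise_sd | 1.0 | unit measurement noise; fixes the correlation scale above |
| effect_slope b | 3.5 (homework per coupling unit) | calibrated so the pooled-cohort r between mean clustering and homework is ≈ 0.3, the order global metrics show in a 51-participant cohort |
| effect_noise_sd | 3.0 (homework units) | behavioural noise dominating the signal, as adherence data demand |
| attendance_slope / sd | 1.2 / 0.8 | same construction on the coarse 0–4 scale |

A null cohort (`simulate_null_cohort`) forces both slopes to 0 and changes
nothing else. A `coupled_networks` override restricts the w_p coupling to a
subset of networks (the rest stay at fixed mean coupling), which makes
enrichment of scan hits in the signal-carrying networks a testable, non-vacuous
property. `group_effect_slopes` lets the two program groups differ.

What the generator does **not** emulate: hemodynamic response, autocorrelated
or 1/f noise, motion artifacts, scanner drift, spatially heterogeneous node
effects within a network, or distance-dependent connectivity. Passing tests
therefore show that the pipeline recovers planted modular structure under
idealized noise — not that it would behave identically on real fMRI.

One structural consequence worth knowing: because every ROI in a coupled
network shares the same w_p, all nodal metrics are attenuated copies of one
global signal. Per-node correlations with adherence are therefore *below* the
pooled global-metric correlation, and the 131 node-level p-values move
together, which makes per-threshold BH selection all-or-nothing on such
cohorts — nodal scans on this generator either light up broadly or not at
all. Real cohorts, with heterogeneous node effects, anchor BH with a few
strong nodes instead. The sign structure of the global scan (positive r for
clustering, local efficiency and segregation; negative for global efficiency)
is the robustly recoverable fingerprint at the default effect size, and the
expected signs flip at very low thresholds (T ≤ 0.10), where low-coupling
participants saturate to near-complete graphs while high-coupling participants
lose between-network edges — a real feature of the model, not a defect.

## Numerical and design notes

* All randomness flows from explicit seeds (`numpy` `SeedSequence` spawning
  for derived streams); no global RNG state is touched. Repetition seeds for
  Louvain and permutation streams for each test are derived deterministically
  from the stage seed.
* Pearson correlations are clipped to [−1, 1] and symmetrized to guard
  rounding; permutation exceedance uses ≥ with a 1e−12 float-noise guard so
  genuinely tied statistics count as extreme.
* The stratified held-out size is round(fraction·n), with class counts within
  1 of proportional.
* Test-suite simulation studies run 20 cohorts per condition at the default
  51 × 131 scale with 1000 (effect) or 200 (null) permutations; brute-force
  oracle suites use ≥ 200 random graphs with n ≤ 12 and exhaustive partition
  search at n ≤ 8. These sizes make Monte-Carlo assertions stable while the
  whole suite stays desk-scale.
* Known limitations: no weighted/signed metric variants, no spatial null
  models (spin tests), no covariate adjustment in the scans, no probability
  calibration or nested hyperparameter search in the classifier. The feature
  set for classification follows the nodal-metric description (clustering and
  degree at robust nodes) rather than any table of global metrics, since only
  nodal features are well-defined per participant at a reference threshold.
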