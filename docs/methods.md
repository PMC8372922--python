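# Methods

## The model

`sigmoid` models an S × N binary matrix σ (samples × variables) as arising
from a super-statistical system: every sample s carries its own K-vector of
intensive variables ("latents") β_s, every variable i a K-vector of energies
("features") E_·i shared across samples, and the probability that variable i
is active in sample s follows the Gibbs–Boltzmann / logistic link

    π_si = exp(−Σ_k β_sk E_ki) / (1 + exp(−Σ_k β_sk E_ki)).

This is the maximum-entropy distribution when the K per-sample energy
averages are constrained, and it is simultaneously a low-rank logistic matrix
factorisation: the modeller chooses only K, the number of constraints; the
constraints themselves (the features) are learned from data. Observations are
conditionally independent Bernoulli(π_si) draws, giving the log-likelihood

    L = Σ_si [σ_si log π_si + (1 − σ_si) log(1 − π_si)]

with exact gradients ∂L/∂β_sk = Σ_i (π_si − σ_si) E_ki and
∂L/∂E_ki = Σ_s (π_si − σ_si) β_sk (with the minus sign inside the exponent,
these are the true ascent directions; the test suite verifies them against
central finite differences).

**Gauge freedom.** For any invertible K × K matrix M, (βM, M⁻¹E) produces
identical probabilities. Parameters are therefore never compared directly;
all recovery statements are made in π-space. The AIC parameter count is
ambiguous for the same reason, so both conventions are reported:
`full` P = K(S+N) and `gauge_corrected` P = K(S+N) − K².

## Fitting

Full-batch gradient ascent with backtracking step halving: a step is accepted
only if L does not decrease, the step grows by 1.2 after every accepted step
and halves on rejection. The accepted-trajectory is therefore non-decreasing
by construction — a testable invariant. Defaults: initialisation i.i.d.
N(0, 0.1²) from a user seed (the degenerate gauge orbit means the solution
reached genuinely depends on initialisation; all entry points are seeded),
stop when the relative improvement falls below `tol = 1e−8` or after
`max_iters = 5000`. Probabilities are clamped to [1e−12, 1 − 1e−12] before
logs so separable (all-zero / all-one) columns cannot produce −∞. An optional
intercept appends a frozen all-ones latent column, giving each variable a
bias energy; it is off by default because the link above has no bias term.

Out-of-sample embedding (`embed_samples`) runs the same ascent on the latent
block only, with features frozen. Held-out samples are scored with the
S-component Bernoulli mixture p(σ) = (1/S) Σ_s Π_i π_si^σi (1−π_si)^(1−σi),
evaluated by log-sum-exp.

## The exact pairwise maximum-entropy comparator

For small systems (N ≤ 20, enforced) the classical pairwise model
p(σ) ∝ exp(−Σ_{i≤j} J_ij σ_i σ_j) is fitted exactly: because σ_i² = σ_i the
diagonal entries act as single-variable fields, giving N(N+1)/2 free
parameters — C(N,2) couplings plus N fields (both counts are surfaced in
outputs). The average negative log-likelihood log Z(J) + Σ J_ij m_ij is
convex with gradient (empirical − model) moments, both computed by
exhaustive enumeration of the 2^N states; it is minimised by L-BFGS and the
moment-matching residual is checked against the requested tolerance
afterwards (a warning is raised if not met). Empirical moments equal to
exactly 0 or 1 would drive multipliers to ±∞; a Laplace pseudocount of 0.5
is applied to such cells only, with a warning. Diagnostics — per-state
probabilities, P(n active), central three-body moments
⟨δσ_i δσ_j δσ_k⟩ — are computed exactly from the enumerated distribution,
and the same diagnostics are available for the logistic model through its
exact (enumerated) state distribution.

## Co-occurrence analyses

* **Richness.** The distribution of per-sample active counts. The model
  prediction is the mean (± SD) over generative replicates of the fitted
  model at the observed S; the independence null is the Poisson-binomial
  distribution of the per-variable occurrence frequencies, computed exactly
  by iterative convolution (O(N²) dynamic programming).
* **Variable clustering.** Euclidean distance between feature columns,
  average-linkage agglomerative clustering by default (single/complete/ward
  available); the full merge tree is kept so flat partitions at any level
  1..N are cheap.
* **Sample clustering.** K-means on latent rows (10 seeded restarts, best
  inertia), with the mean silhouette score and a sweep helper.
* **Tests.** Enrichment of an annotation inside a cluster: one-tailed
  hypergeometric upper tail. Pairwise association: sign of the phi
  coefficient plus a one-sided Fisher exact p-value for positive association
  (exactness matters at low presence counts). Differential occurrence of a
  variable in a sample cluster: hypergeometric upper tail of its in-cluster
  count given its margin. Raw p-values are reported; Benjamini–Hochberg is
  available but off by default.

## Cluster-based imputation of masked variables

To predict variables hidden by incomplete observation (the motivating case:
reactions missing from draft metabolic reconstructions), a fraction of each
test sample's positives is masked (round-half-away-from-zero of
fraction × positives, at least one when two or more positives exist, zeros
never touched) and the rule "if any retained positive lies in a cluster,
predict every member of that cluster present" is applied at each dendrogram
cut level. Sweeping the level from all-singletons (predict nothing new) to
one-cluster (predict everything) traces an ROC curve; per-sample TPR/FPR are
averaged across samples ("averaged across all bacteria"), anchors (0,0) and
(1,1) appended, and AUC computed by the trapezoid rule. The same sweep
yields the mean Jaccard overlap against the true positive set versus the
relative predicted size; the peak sits near relative size 1.

The rule has an intrinsic specificity limit worth stating: a foreign cluster
is falsely activated whenever a single stray retained positive lands in it,
so the expected count between_rate × cluster_size × retained_fraction must be
well below 1 for the block-level ROC point to sit near the top-left corner.
The planted-block fixtures used for validation are chosen in that regime
(6 blocks of 20 variables, within-block presence 0.95, cross-block 0.002),
i.e. strongly modular structure of the kind metabolic pathways exhibit.

## Synthetic data

Planted models draw β and E i.i.d. Gaussian; at unit scales and K = 3 the
probabilities span roughly (0.03, 0.97). Block fixtures activate a sample
cluster's own variable block with `within_p` and everything else with
`between_p`, returning the true partitions. Generators are pure functions of
their seeds. What these fixtures do **not** emulate: temporal correlation
between samples (spike trains), phylogenetic relatedness (genome
collections), or margin heterogeneity beyond what the logistic link induces —
so passing recovery tests demonstrate correctness of the machinery, not
robustness to those real-data complications.

The richness benchmark uses S = 1400 samples (the scale of the micron-scale
particle dataset this analysis emulates) of N = 80 variables from a K = 2
model with parameter scale 2.0, a strongly over-dispersed regime in which
the model/null contrast exceeds the sampling noise of a single empirical
richness curve; at weaker scales individual parameter draws can be close
enough to independence that the comparison is uninformative.

## Numerical choices and limitations

* Clamping at 1e−12 bounds the likelihood on separable data; it also means a
  "perfect" fit reports L = SN·log(1−1e−12) rather than 0.
* The enumeration cap N ≤ 20 keeps exact computations at desk scale; larger
  N raises an error rather than silently approximating.
* `fcluster(..., 'maxclust')` may merge tied heights; requesting L clusters
  can return fewer when distances are degenerate.
* Two properties of the *statistics themselves* (not the implementation)
  deserve note, established with an independent fully-converged optimiser as
  cross-check. First, ML recovery of π at S=200, N=50, K=3 with unit-scale
  parameters is capped near r ≈ 0.93 even when the true features are known,
  because each sample's 3 latents must be estimated from 50 binary draws;
  full ML lands near r ≈ 0.87. Second, AIC with P = K(S+N) under-penalises
  latent dimension at strongly rectangular shapes such as 500 × 80: the
  likelihood gain of an extra component fitted to pure noise behaves like
  the random-matrix edge (√S + √N)²/2 times a logistic factor, which exceeds
  S + N there, so the AIC curve keeps decreasing past the planted K. At the
  1406 × 347 shape of the particle dataset the inequality reverses, which is
  why a finite AIC optimum exists in that regime. Held-out predictive
  scoring (`cross_validate`) is the more reliable selector at rectangular
  shapes.
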