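# Methods

## The Betti-0 curve of a correlation network

For one subject, the connectome is a symmetric matrix of Pearson
correlations *r* between *n* regional signals with unit diagonal; all
topology is computed on the dissimilarity *d* = 1 − *r* ∈ [0, 2]. Sweeping
the filtration value ε from 0 upward, an edge (*i*, *j*) is present once
*d*(*i*, *j*) ≤ ε (non-strict, so B₀ is right-continuous and ties are
well defined; at ε = 0 only exactly duplicated nodes are connected and
B₀(0) = *n* for generic data). B₀(ε) is the number of connected components
of the threshold graph. The curve is fully determined by the *n* − 1
merge values — the thresholds at which two components join — which equal
the sorted edge weights of a minimum spanning tree of *d* (single-linkage
dendrogram heights). We compute them with a Kruskal scan over edges in
ascending weight using union-find with path compression and union by
rank; ties are broken by (*i*, *j*) index, which cannot change any B₀
value, only which tied edge is recorded as the merger. Tied merges are
kept as repeated values, never jittered. An independent oracle
(single-linkage heights from `scipy.cluster.hierarchy` and per-threshold
component counts from `scipy.sparse.csgraph`) verifies the computation in
the test suite; it is never the implementation.

Negative correlations are kept (*d* up to 2) rather than truncated: the
*d* = 1 − *r* map is applied as stated, without a truncation step.

## Curve features

- **AUC**: the exact piecewise integral of the B₀ step function over the
  fixed domain [0, 2] — the full range of *d* — for every subject and
  every node subset. A fixed domain keeps areas comparable across
  subjects: the flat B₀ = 1 tail after the last merge adds the same
  constant to everyone and so cancels from group contrasts.
  Algebraically AUC = (domain length) + Σ merge values, which the tests
  use as an exact independent oracle.
- **slope**: the ordinary-least-squares slope of the points (ε, B₀(ε))
  sampled at ε = 0 and at every merge value (ties included, so repeated
  merges weight the fit). OLS over the whole staircase was chosen over
  the two-point secant because the feature is meant to capture the
  curve's overall rate of change; the secant variant discards everything
  between the endpoints. The choice is isolated in one function so the
  secant can be swapped in.
- **kurtosis**: the excess kurtosis (Fisher, bias-uncorrected m₄/m₂² − 3)
  of the merge-value distribution. The alternative reading — kurtosis of
  the curve's ordinate values — was rejected because the ordinates of a
  B₀ curve are a fixed staircase from *n* to 1 whose shape barely varies;
  the distribution of merge (death) values over ε is what distinguishes a
  sharp transition from a drawn-out one, with more concentrated merges
  giving higher kurtosis.

Degenerate inputs raise `DegenerateCurveError`: slope needs ≥ 2 nodes and
at least one non-zero merge; kurtosis needs ≥ 4 merge values with
non-zero variance.

## Rewiring null model

A surrogate connectome permutes the off-diagonal weights over the edge
positions of the complete graph (mirrored to keep symmetry, diagonal
fixed at 1), conserving the weight multiset exactly — hence every moment
of the weight distribution — while destroying community topology. On a
complete weighted graph, degree-preserving edge-swap rewiring reduces to
exactly this weight shuffle; the default implementation performs 10·E
seeded pairwise transpositions of upper-triangle entries (E = n(n−1)/2)
to keep the rewiring semantics explicit, and a `mode="shuffle"` switch
draws one uniform permutation directly (statistically equivalent,
faster). The ensemble default is 1000 permutations per subject.
Per-permutation seeds are spawned from the master seed by counter, so
ensembles are bit-for-bit reproducible and order-independent. Empirical
p-values use the add-one rule p = (1 + #{null at least as extreme}) /
(1 + n_perm), with two-sided p twice the smaller one-sided p, capped at 1.
Per-subject p-values are the primitive; any pooling across subjects is
left to the caller.

## Group inference

The whole-brain model is a maximum-likelihood logistic regression,
`group ~ auc + kurtosis + slope + sex + age + motion`, fitted with
statsmodels. Dimensional terms are standardised to z scores (sample SD)
over the full analysis sample — once, not per subnetwork — so odds
ratios are per SD; sex enters as a raw binary indicator and group is
coded case = 1. Wald per-term p-values and 95% intervals are reported,
matching standard logistic summaries. Separation and non-convergence are
flagged on the result, never silently swallowed.

The subnetwork scan re-fits the same model on each of the k(k+1)/2 node
subsets of a partition: the k single networks and all pairs, a pair
taken as the union of both networks' nodes so that intra-network edges
of both members take part in the filtration. Networks with fewer than 5
nodes are marked unevaluable rather than aborting the scan. For
family-wise error control, cells significant at α = 0.05 are mapped onto
a network-of-networks graph (networks as vertices, internetwork cells as
edges, intranetwork cells as self-loops); clusters are connected
components, the cluster statistic is the number of significant cells,
and the null distribution of the maximal cluster statistic comes from
re-fitting all cells under diagnostic-label permutation (covariates stay
attached to their subjects — the outcome is what is exchangeable under
the null). Subset features do not depend on the labels, so they are
computed once and only the logistic fits are repeated, which is what
makes 10⁴ permutations (the default) tractable. Cluster p-values use the
add-one rule and cannot fall below 1/(1 + n_perm).

Edge-level contrasts compare, per edge and threshold, the proportion of
subjects in each group for whom the edge is present (d ≤ ε), with the
pooled two-proportion z-test, two-sided, masked at p < 0.01 uncorrected;
edges with zero pooled variance report p = 1. Default thresholds:
ε ∈ {0.35, 0.5, 0.75, 1.0}.

Descriptive effect sizes mirror a phenotype table: Cohen's d from group
summaries with the pooled SD, and the cross-product odds ratio of a 2×2
table with the Haldane–Anscombe +0.5 correction when a single cell is
zero. Note that for the published sex counts (51/45 vs 22/59) the
cross-product gives 3.04 while the table prints 3.019; the estimator
behind the printed value is not stated, and this package reports the
cross-product rather than tuning to it.

## Concordance across parcellations

Kendall's W treats each parcellation as a rater ranking the subjects by
a curve feature: ranks with mid-rank ties, the standard (t³ − t) tie
correction, W = 12S / (m²(n³ − n) − mΣT). Significance uses the χ²
approximation χ² = m(n − 1)W on n − 1 degrees of freedom, matching the
reporting convention for samples of this size; a seeded permutation
p-value is available for small n. The smallest W significant at level α
is χ²₁₋α,ₙ₋₁ / (m(n − 1)) — 0.59 for two raters and 177 subjects at
α = 0.05.

## Synthetic cohorts

Each subject's regional signals follow a latent factor model: node *i* in
community *c* has x_i(t) = w_i f_c(t) + b_i g(t) + e_i(t), with one
factor per community, one global factor, unit noise, all i.i.d. standard
normal over t = 172 time points (a typical 6-minute resting-state scan
after volume removal). The implied population correlation is
positive-definite by construction and the Pearson connectome of the
finite sample inherits realistic estimation noise. Defaults: 96 controls
and 81 cases; 116 nodes in 7 communities (an anatomical-atlas-like
layout); within-community loading w = 0.8 and global loading b = 0.35,
giving population correlations of about 0.44 within and 0.09 between
communities — a clear but not extreme community structure. Covariates
are drawn per group with the magnitudes of a pediatric case-control
sample: a ≈3:1 male-predominance odds ratio in cases, cases ≈1.8 years
younger, slightly higher head motion, plus symptom-score and IQ columns,
so confound-adjustment code paths are always exercised.

Two case effects are available, both confined to `target_networks` when
given:

- `effect_between` raises the global loading b, increasing long-range
  connectivity. It lowers AUC but, because it compresses the whole merge
  distribution, it shifts the slope almost one-for-one with the AUC.
- `effect_within` raises the community loading w, increasing short-range
  (within-community) connectivity. Communities condense at lower
  thresholds, lowering AUC, while the between-community tail of the
  curve — which anchors the slope — stays put. This reproduces the
  empirical case-control pattern this pipeline targets: a clear AUC
  difference with no slope difference, and short-range edges more often
  present in cases at low thresholds.

`effect_within = 0.013` at the default scale was calibrated once, by
pilot simulation, to lower case AUC by ≈0.5 SD (the effect size the
recovery analyses are specified at), and `0.1` is used for the
localization experiments with the effect confined to one community.
Per-subject seeds are spawned from the master seed by counter, so
cohorts are reproducible and parallel-safe. `refine_partition` splits
community labels to emulate finer parcellations of the same nodes;
`atlas_view` restricts every subject to one seeded node subset to
emulate a genuinely different atlas for concordance analyses (the B₀
features of the whole node set do not depend on partition labels, so
label refinement alone cannot create a second rater).

## What the generator does and does not emulate

It reproduces: two diagnostic groups with realistic covariate imbalance,
community-structured positive-definite correlation matrices with
sampling noise, group effects of controllable size and localisation, and
multiple-parcellation views of one cohort. It does not reproduce:
hemodynamic autocorrelation (time points are i.i.d., so feature
variances are somewhat optimistic for a given scan length), motion
artefacts or their correlation with connectivity, negative population
correlations, hubs or hierarchical module structure, or the wide
correlation range of real rsfMRI (synthetic r stays below ≈0.5, so
edge-presence contrasts are informative at higher ε than in real data).
Passing tests therefore demonstrate correctness and calibration of the
pipeline on well-behaved community-structured input, not performance
under realistic physiological noise.

## Simulation sizes and numerical choices

Calibration and recovery suites run at reduced problem sizes, chosen as
the smallest that leave the conclusions stable: type-I error uses 500
replicates of the inference stage at n = 177 with features drawn
independent of diagnosis; FWE false-positive control uses 100 null
cohorts of 80 subjects, 36 nodes, 3 communities at 200 permutations;
effect recovery uses 200 cohorts at full study scale (177 subjects, 116
nodes); localisation uses 100 cohorts of 80 nodes in 4 communities. The
acceptance script runs the full pipeline once at study scale with 200
null and FWE permutations. Matrix symmetry up to 1e-6 is tolerated on
file input (entries averaged); larger asymmetry is an error. Diagonals
in input files are ignored and forced to 1 (r) or 0 (d). All randomness
flows from explicit seeds through numpy `SeedSequence` spawning.

## Known limitations

Wald inference can be anticonservative in small subnetwork samples;
cells that fail to converge are reported as NaN and treated as
non-significant rather than imputed. The χ² approximation for Kendall's
W is asymptotic in n. The cluster-FWE procedure controls the rate of
any false cluster under label exchangeability; covariate-dependent group
assignment (confounding by design) is handled by keeping covariates in
the permuted model, not by restricted permutations.
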