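# topoconnect

Topological data analysis of functional connectomes: Betti-0 curves of the
Rips filtration, scalar curve features, rewiring null models, and
permutation-based case-control inference at whole-brain and subnetwork
levels.

## The problem

A functional connectome is the node-by-node matrix of Pearson correlations
*r* between regional brain signals. Graph-theoretic analyses of such
networks depend on an arbitrary connectivity threshold and on the chosen
parcellation, which has produced inconsistent case-control findings.
Instead of fixing one threshold, this package sweeps them all: with the
dissimilarity *d* = 1 − *r*, an edge (*i*, *j*) exists at filtration value
ε once *d*(*i*, *j*) ≤ ε. The zeroth Betti number B₀(ε) — the number of
connected components of the threshold graph — starts at the node count *n*
at ε = 0 and decreases to 1 as ε grows. The resulting B₀ curve is a
threshold-free description of network topology, summarised by three
scalars:

- **AUC** — the exact integral of the step function over ε ∈ [0, 2]
  (equivalently 2 + Σ of the *n* − 1 component-merge values, which are the
  minimum-spanning-tree edge weights of *d*). Smaller AUC means the network
  condenses into one component at lower thresholds: less segregation.
- **slope** — the least-squares rate of change of B₀ against ε; always
  negative, lower values mean a faster transition.
- **kurtosis** — the excess kurtosis of the merge-value distribution;
  higher values mean merges concentrate around their mean.

Group inference uses logistic regression with standardised terms,

    group ~ AUC + kurtosis + slope + sex + age + motion

reported as per-SD odds ratios with Wald intervals. The same model is
re-fitted on every intranetwork and internetwork node subset of a
partition (k(k+1)/2 cells for k networks, internetwork cells taken as the
union of both networks' nodes); clusters of significant cells on the
network-of-networks graph receive family-wise-error-corrected p-values by
permuting diagnostic labels, network-based-statistic style. Rewired
surrogates (weight-multiset-preserving) provide a per-subject null for the
curve features, Kendall's W quantifies cross-parcellation agreement, and a
synthetic factor-model cohort generator makes the whole pipeline testable
without any imaging data.

## Worked example

```python
import topoconnect as tc

# a synthetic case-control cohort: 96 controls, 81 cases, 116 nodes in
# 7 communities; cases get a within-community connectivity increase that
# lowers their Betti-0 AUC by about 0.5 SD
spec = tc.CohortSpec(effect_within=0.013, seed=1)
connectomes, phenotypes, partition = tc.simulate_cohort(spec)

features = tc.features_table(connectomes, phenotypes["subject_id"])
print(features.head(3).round(3))

model = tc.fit_group_model(features, phenotypes)
print(model.summary_frame().round(3))
```

```
  subject_id     auc    slope  kurtosis
0   sub-0000  59.115 -332.759     4.969
1   sub-0001  60.650 -345.326     3.432
2   sub-0002  59.473 -309.289     6.924

       term   beta     or  ci_low  ci_high      p
0     const -0.822  0.439   0.262    0.736  0.002
1       auc -0.416  0.660   0.467    0.932  0.018
2  kurtosis  0.322  1.380   0.873    2.181  0.168
3     slope  0.088  1.092   0.700    1.703  0.698
4       sex  1.098  2.998   1.527    5.887  0.001
5       age -0.347  0.707   0.504    0.990  0.044
6    motion  0.113  1.120   0.806    1.555  0.500
```

The AUC odds ratio of 0.66 per SD (p = 0.018) recovers the implanted
effect: cases have smaller areas under the B₀ curve — their connectomes
integrate into a single component at lower filtration values — after
adjusting for sex, age and head motion. A subnetwork scan
(`tc.subnetwork_scan`), rewired nulls (`tc.null_features`,
`tc.empirical_p`), edge-presence contrasts (`tc.edge_proportion_scan`) and
cross-parcellation concordance (`tc.pairwise_kcc`, `tc.kcc_critical`)
follow the same pattern; `topoconnect pipeline --out run/ --seed 1` runs
every stage from the shell and writes CSV artifacts plus a JSON manifest.

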