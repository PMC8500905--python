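# scovnet

Structural covariance network analysis of regional cortical thickness.

When cortical thickness is measured in the 68 regions of the
Desikan-Killiany atlas across the subjects of a diagnostic group, regions
whose thickness co-varies across subjects are considered "connected": the
group's *structural covariance network*. `scovnet` implements the full
graph-theoretical workflow used to compare such networks between a
patient group and controls — for example in dementia with Lewy bodies
(DLB) versus healthy ageing — starting from a plain per-subject thickness
table and ending in tidy, reproducible reports.

## The method

For each group and region *j*, thickness is residualized by OLS,

&nbsp;&nbsp;*t*<sub>*ij*</sub> = α<sub>*j*</sub> + β<sub>age</sub>·age<sub>*i*</sub> + β<sub>sex</sub>·sex<sub>*i*</sub> + β<sub>edu</sub>·edu<sub>*i*</sub> + β<sub>mct</sub>·mct<sub>*i*</sub> + ε<sub>*ij*</sub>,

with mct the subject's mean cortical thickness. The 68×68 association
matrix holds the Pearson correlations *r*<sub>*jk*</sub> of the
residuals; binarizing at network density *D* keeps the
*E* = round(*D*·68·67/2) strongest (signed) correlations as edges of a
binary undirected graph, for *D* = 9–24% in 1% steps (342 edges at the
15% reference density). On each graph the package computes

* **global** measures — characteristic path length *L*, global
  efficiency *E*<sub>glob</sub> (mean inverse shortest path), local
  efficiency, mean clustering coefficient *C*, Newman–Girvan modularity
  *Q*, and the small-world index σ = (*C*/*C*<sub>rand</sub>)/(*L*/*L*<sub>rand</sub>)
  against degree-preserving rewired nulls;
* **nodal** measures — nodal efficiency, nodal clustering, and
  Wasserman–Faust closeness centrality.

Group differences are assessed by permuting diagnosis labels and
re-running the entire chain (residualization included) for each shuffle,
with two-tailed *p* = (1 + #{|null| ≥ |obs|})/(*n*<sub>perm</sub> + 1) and
Benjamini–Hochberg FDR across the 68 nodes for nodal measures. Community
structure is detected with restart-best-*Q* Louvain at *D* = 15%, modules
are matched across groups by optimal overlap assignment, and matched
modules are scored with the Jaccard index (and the shared-fraction
variant |∩|/(|A|+|B|), common in the applied literature).

A first-class synthetic-cohort generator
(`scovnet.simulate.generate_cohort`) plants known covariate effects,
4-module latent-factor covariance, global patient thinning and
attenuated/rewired patient module structure, so every stage of the
pipeline can be validated against ground truth.

## Worked example

The package ships a 68-region module-assignment table from a published
control-vs-DLB comparison. Scoring the numeral-matched modules:

```sh
$ scovnet reproduce-table2
 module_a  module_b  n_a  n_b  n_shared  n_union   jaccard  shared_fraction
        1         1   18   22         8       32 25.000000        20.000000
        2         2   19   18         6       31 19.354839        16.216216
        3         3   11   14         3       22 13.636364        12.000000
        4         4   20   14         5       29 17.241379        14.705882
```

Module IV, for instance, has 20 control regions and 14 patient regions of
which 5 coincide: shared fraction 100·5/34 = 14.7%. The low coefficients
for every module quantify how extensively the patient group's community
structure is reorganized relative to controls.

On a synthetic cohort (23 controls vs 24 patients, default disruption
parameters):

```python
>>> import scovnet as s
>>> cohort, truth = s.generate_cohort(s.SimulationParams(seed=7))
>>> res = s.residualize(cohort)
>>> for grp in ("control", "patient"):
...     g = s.threshold_by_density(s.association_matrix(res, grp), 0.15)
...     gm = s.global_metrics(g, n_random=50, seed=0, louvain_seed=0)
...     print(grp, f"C={gm.mean_clustering:.3f} Q={gm.modularity:.3f} "
...           f"sigma={gm.small_world_sigma:.2f}")
control C=0.513 Q=0.578 sigma=2.79
patient C=0.287 Q=0.351 sigma=1.97
>>> r = s.permutation_test(cohort, "clustering", 0.15, n_perm=1000, seed=0)
>>> print(f"clustering diff {r.observed:+.4f}, p={r.p_value:.4f}")
clustering diff -0.2254, p=0.0020
```

The planted patient disruption (attenuated module loadings) lowers
clustering, modularity and small-worldness, and the permutation test
detects the clustering deficit — the qualitative signature reported for
DLB cohorts.

The full pipeline (`scovnet analyze --input cohort.tsv --out run/`, or
`run_pipeline(RunConfig(...))` from Python) writes association matrices,
per-density metric tables, permutation results with FDR, partitions, the
module comparison and a per-region allocation table, plus a manifest that
reproduces the run bit-for-bit.

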