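# Methods

## Scope and data model

`scovnet` analyses group-level structural covariance networks built from
regional cortical thickness. Its sole input is a tidy cohort table: one
row per subject with a `control`/`patient` label, age (years), sex (0/1,
1 = female), education (years), and 68 thickness values (mm) keyed to
the Desikan–Killiany parcellation (34 regions × 2 hemispheres,
FreeSurfer `aparc` names with `lh_`/`rh_` prefixes). The packaged atlas
fixes the canonical region order — left hemisphere then right, grouped
into frontal, temporal, parietal, occipital and cingulate blocks — and
every matrix and nodal vector in the package indexes against it, so the
output is invariant to input column order. Thickness values outside the
(0.5, 5.0) mm plausibility band are validation errors on file input,
never silent drops; the simulator bypasses the band because extreme
stress-test regimes legitimately exceed it.

## Residualization

Each region is regressed on an intercept plus the configured covariates
(default: age, sex, education, mean cortical thickness) by ordinary
least squares, and the residuals carried forward. Two conventions are
deliberate:

* **Mean cortical thickness** is the unweighted mean over the 68
  parcels, recomputed from the table, since parcel surface areas are not
  part of the input. Published workflows do not always state whether
  their global mean is area-weighted; the difference is small, but the
  convention is pinned here.
* **Fit scope** defaults to `per_group` — each group's association
  matrix comes from fits within that group — with `pooled` available.
  The per-group choice prevents one group's covariate structure from
  contaminating the other's network; the permutation test refits inside
  every shuffle under this scope so that label-dependent fits cannot
  leak.

Rank-deficient designs are rejected with the offending covariate named.
Residualization is exactly idempotent for fixed covariates; with the
mean-thickness covariate the second pass recomputes the mean from the
residuals themselves, so idempotence holds only for the fixed-covariate
case, and the tests assert it there.

## Networks

The association matrix is the Pearson correlation of residuals across
the subjects of one group (minimum 3; zero-variance regions are errors).
Thresholding at density *D* keeps the *E* = round(*D*·*N*(*N*−1)/2)
pairs with the **largest signed r** (half-up rounding; at *N* = 68,
*D* = 15% gives *E* = 342 and *D* = 9% gives 205 ≥ *N*). Ranking by
signed rather than absolute correlation treats anticorrelations as
non-edges, the prevailing structural-covariance convention; the sweep
validity report tabulates how many retained edges would differ under
|r| ranking so the choice is visible in the data at hand. Ties are
broken by ascending (i, j) pair, making thresholding deterministic, and
edge sets nest across the sweep by construction. The default sweep is
9–24% in 1% steps (16 graphs); the validity report flags, per density,
disconnectedness and a small-world index below 1.5 — the two criteria
used to justify such a range.

## Graph measures

All metrics are implemented directly from their definitions on boolean
adjacency matrices (BFS distances via `scipy.sparse.csgraph`; triangle
counts via matrix products) and are verified in the test suite against
exhaustive brute-force recomputation on 200 random graphs of ≤ 8 nodes
and against independent library implementations.

* Global efficiency: mean of 1/d over ordered pairs, 1/∞ = 0 — the
  integration measure of choice for possibly disconnected graphs.
* Local efficiency: per node, the global efficiency of the subgraph on
  its neighbours (0 below degree 2). Some published texts describe
  "local efficiency" with the *average inverse shortest path length*
  wording, which is the global-efficiency formula; both quantities are
  computed and reported so either reading can be compared.
* Clustering: C_i = 2·triangles/(deg·(deg−1)), mean over nodes.
* Characteristic path length: mean over finite pairs, with the count of
  infinite pairs reported rather than folded into the mean.
* Closeness: Wasserman–Faust form (r−1)²/((N−1)·Σd), which scales
  within-component closeness by component size and is 0 for isolated
  nodes.
* Modularity: Newman–Girvan Q over an explicit partition; verified
  against the pairwise-sum formulation.
* Small-world index: σ = (C/C_rand)/(L/L_rand) with C_rand, L_rand
  means over degree-preserving rewired graphs (10·E swap attempts per
  null, default 100 nulls). The unnormalized L/C ratio is also emitted:
  published "small-world index ≥ 1.5" thresholds are only meaningful for
  the normalized form, but the literal ratio appears in some method
  descriptions.

## Community structure

Louvain (networkx implementation, resolution 1) is run with
`n_restarts` seeds derived from one integer seed; the partition with the
highest Q is kept, which makes detection deterministic and monotone in
the number of restarts. Louvain is greedy: on small sparse graphs it can
sit below the exhaustive-search optimum (the tests document a 7-node
counterexample), which is why Q-critical results use many restarts. The
reference density is 15%, the midpoint of the sweep.

Cross-group module correspondence is a maximum-total-overlap assignment
(Hungarian algorithm on shared-region counts); surplus modules match an
empty pseudo-module. Matched modules are scored two ways:

* **Jaccard**, 100·|∩|/|∪| — a true similarity index, 100 iff the
  region sets coincide;
* **shared fraction**, 100·|∩|/(|A|+|B|) — the "shared regions over
  total regions attributed by both groups" convention, bounded by 50.

Both appear in every report because applied papers frequently print the
second under the first's name.

### The worked example and its discrepancy

The packaged worked-example table transcribes a published control-vs-DLB
module assignment (68 regions, labels I–IV per group). The published
typesetting is ambiguous for 14 rows; the transcription resolves those
rows from the same publication's prose description of module membership,
with remaining ties broken toward the published similarity coefficients.
Scoring numeral-matched modules with the shared-fraction formula gives
20.0, 16.2, 12.0 and 14.7% for Modules I–IV. The fourth value reproduces
the published figure exactly (5/34); the other three published values
(17.6, 20, 7.1) are **not reproducible from the published table under
any reading** — an exhaustive search over every transcription ambiguity,
set convention (region-hemisphere pairs vs region names), denominator
(union, sum, min, max, single group) and module correspondence shows,
for example, that the third module's published 7.1% requires 28 total
attributions where the table permits at most 27. The package therefore
reports what the printed table actually yields and documents the
mismatch rather than adjusting either side.

## Permutation inference

Because group-level networks provide no subject-level variance, the
group difference statistic is the plain metric difference
(patient − control) and its null distribution comes from shuffling
diagnosis labels and recomputing the full chain per shuffle. The
two-tailed p-value uses add-one smoothing, so p ≥ 1/(n_perm+1) and is
never 0. The default n_perm is 5000; nodal families are BH-corrected at
q < 0.05 per metric per density across the 68 nodes (the FDR family is
recorded in the run manifest). A random-graph comparison reports
z-scores of observed metrics against Erdős–Rényi and degree-preserving
ensembles as a consistency check on significant findings.

Calibration, measured by the acceptance suite: under an exchangeable
null cohort of 23 vs 24 subjects, 1000 repetitions at n_perm = 200 give
an empirical type-I error of 0.045 at α = 0.05 with p-values
indistinguishable from uniform (KS p = 0.92).

## Synthetic cohorts

The generator draws, per subject, age ~ U(60, 90), sex ~ Bernoulli(0.25
female), education ~ U(8, 19), module factors f ~ N(0, 1), and sets

    t_ij = baseline_j + beta_age*age + beta_sex*sex + beta_edu*edu
           + loading_j * f_{m(j)} + eps_ij,      eps ~ N(0, noise_sd²)

Patients are shifted by −`patient_global_thinning`, their loadings
multiplied by (1 − `patient_loading_attenuation`), and a fraction of
their regions reassigned to random modules before the factors apply.
All randomness flows from a single `numpy.random.Generator` seeded by
one integer, so identical parameters yield byte-identical tables.

Defaults describe a realistic single-centre dementia case-control
cohort: 23 controls vs 24 patients; baseline 2.5 mm; β_age = −0.005
mm/yr, β_sex = 0.02 mm, β_edu = +0.005 mm/yr (education associates
positively with thickness); 4 equal modules with within/cross loadings
0.12/0.03 and regional noise 0.10 mm, which put within-module residual
correlations near 0.6 against 0.3 across modules; global thinning
0.12 mm, the mean-thickness gap typical of DLB vs control cohorts
(2.25 vs 2.37 mm); attenuation 0.5 and scramble fraction 0.25 for a
clearly disrupted but not degenerate patient network.

The generator emulates covariate confounding and modular covariance; it
does **not** emulate spatially autocorrelated measurement noise,
hemispheric asymmetries, scanner/site effects, non-Gaussian thickness
distributions, or lobe-specific atrophy gradients. Passing tests
therefore demonstrate that the pipeline recovers what the latent-factor
model plants, not that real cohorts carry equally clean structure.

### Problem sizes in the test and acceptance suites

Monte-Carlo experiments use sizes chosen to bound the full suite at a
few minutes of one CPU: calibration runs 1000 cohorts at n_perm = 200;
the planted-recovery experiment uses 20 seeds at n = 200/group with
within-module loading 0.8 over noise 0.05 and 10 Louvain restarts; power
and uniformity smoke tests use smaller replicate counts. One subtlety is
documented by the modularity-direction experiment: at n = 200 with
near-noiseless loadings, density thresholding saturates — even strongly
attenuated patient correlations (r ≈ 0.9) exceed every cross-module
correlation, the retained edge set stays entirely within modules in both
groups, and binary-graph modularity cannot express the attenuation. The
decreased-modularity signature is therefore asserted at the realistic
cohort scale (23 vs 24), where sampling noise lets cross-module edges
displace within-module ones; there it holds in 20/20 seeds.

## Known limitations

* Binary undirected graphs only; no weighted-network variants.
* No consensus clustering across densities; module detection is pinned
  to one reference density.
* No bootstrap confidence intervals on metrics and no covariate
  interaction inference; the permutation test addresses exactly the
  two-group exchangeability question.
* Louvain is a heuristic; best-of-restarts controls but does not
  eliminate suboptimality.
* No parsing of FreeSurfer output trees; users export a thickness table.
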