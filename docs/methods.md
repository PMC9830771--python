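# Methods

`scnet` implements group-level structural covariance network analysis:
from tables of per-subject regional grey-matter volumes to
graph-theoretic group comparisons with permutation inference.

## The model

A structural covariance network is a property of a *group*, not of a
subject.  Its nodes are `N` named brain regions (by default the 116
regions of the AAL parcellation); the weight of edge `(i, j)` is the
Pearson correlation of regions `i` and `j`'s volumes *across the
subjects of one group*.  Before correlating, each region is
residualized on nuisance covariates (age and sex) by ordinary least
squares with an intercept; correlating residuals is equivalent to
partial correlation given these covariates.

Binary graphs are obtained by density thresholding: at density `d` the
`k = round(d·N(N−1)/2)` most strongly *positively* correlated pairs
become edges.  Negative correlations never become edges — conventional
for grey-matter covariance, and necessary for "strongest connections"
thresholding to be meaningful.  Rank ties are broken lexicographically
by (row, col) so results are bit-reproducible.  Analyses run on a grid
from `d_min` — the smallest grid density at which **every** compared
network forms a single connected component — to an upper bound of 0.5,
beyond which covariance networks lose biological specificity.  The
default grid step is 0.01; the step is recorded in all output
metadata because AUC values depend on it (mildly, at O(step²)).

### Graph measures

* Clustering coefficient `C`: per node, realized / possible edges
  among its neighbours (degree < 2 contributes 0); `C` is the mean.
* Characteristic path length `L`: mean shortest-path hop count over
  node pairs.  On a disconnected graph, `L` is computed on the largest
  connected component and the event is flagged — this arises only in
  permutation replicates, because observed grids start at `d_min`.
* Small-world index `σ = (C/C_rand)/(L/L_rand)`, with `C_rand`,
  `L_rand` ensemble means over `n_random = 20` degree-preserving
  random references produced by connectivity-preserving double-edge
  swaps (Maslov–Sneppen style), 10 swap attempts per edge.  All three
  null-model parameters are configurable and logged.
* Nodal betweenness centrality, normalized by `(N−1)(N−2)/2`.  Hubs
  are regions with betweenness ≥ mean + 2·SD across regions; the SD is
  the population (n-denominator) SD by default, with the sample
  convention available (the hub rule is scale-invariant, so the
  normalization is presentational).  Nodal summaries and hub maps are
  reported at `d_min`, where the graph is just fully connected.

Implementation: clustering by dense matrix algebra, path lengths via
`scipy.sparse.csgraph`, betweenness via igraph's Brandes
implementation, rewiring via `networkx.connected_double_edge_swap`.
The test suite checks all three measures against brute-force
enumeration oracles on random graphs of ≤ 12 nodes.

### Permutation inference

Group networks cannot be compared subject-wise, so inference permutes
*subjects* and recomputes the entire pipeline (residualize →
correlate → threshold → measure) for each relabeling:

* unpaired (patients vs controls): pooled subjects are reassigned
  uniformly at random to pseudo-groups of the original sizes;
* paired (baseline vs follow-up): each subject's two timepoint labels
  are swapped independently with probability 1/2 (a sign-flip scheme
  respecting the pairing).  An unpaired fallback is available, since
  published descriptions of the toolbox methodology do not state the
  paired scheme.

Per-density differences are summarized by the trapezoidal area under
the curve (AUC) over `[d_min, 0.5]`, making the test robust to any
single threshold choice.  Two-tailed p-values use
`(#{|perm| ≥ |obs|} + 1)/(n_perm + 1)` (never exactly zero; default
`n_perm = 1000`).  `d_min` is fixed from the observed data and reused
in replicates; replicates that happen to be disconnected at `d_min`
(or to run out of positive correlations near density 0.5) fall back to
the largest-component / clipped-edge-set convention and are counted in
the result.  Recomputing `d_min` per replicate is available as an
option.  Per-region p-values are Benjamini–Hochberg FDR-adjusted
across the regional tests only; the (three) global-measure tests are
not pooled with them.  Both raw-p and q maps are always reported,
since regional effects frequently fail FDR at these sample sizes.

The permutation loop operates on raw numpy arrays with a canonical
subject ordering, which makes `compare()` bit-reproducible for a fixed
seed and exactly symmetric under swapping which group is called "A".

### Clinical statistics

Two-sample t-tests run directly from published-style summaries (mean,
SD, n); Welch is the default and Student's pooled test is available,
since demographic tables rarely state the convention.  The 2×2
chi-squared test is uncorrected Pearson by default (Yates optional).
The two-timepoint, two-group repeated-measures ANOVA uses the
classical mixed-design decomposition (group tested against
subjects-within-groups; time and group×time against the
time-by-subject residual); with two timepoints sphericity is trivially
satisfied.  The sums of squares partition the total exactly, which the
tests assert, and the F statistics are cross-checked against pingouin.

## The synthetic cohort generator

No deposited volume tables exist for this class of study, so the
generator produces cohorts with fully known population structure.  Per
subject,

    volume_r = 1.0 + age_slope·(age − age_mean) + sex_offset·(sex − ½) + ε_r,
    ε ~ MVN(0, noise_sd²·R),

with volumes in arbitrary units around a grand mean of 1.0 (volumes
are positive; generation truncates at 0 with a warning, which never
triggers at default SDs).  Defaults: `noise_sd = 0.05`,
`age_slope = −0.003`/year (grey matter shrinks slowly with age),
`sex_offset = 0.05`, age ~ N(25, 5²) years, 20 subjects/group, sex
allocated 50/50 within group.

`R` is a block correlation matrix: blocks of 6 regions with
within-block correlation `rho_in = 0.3` and background `rho_out = 0.1`
(configurable), a coarse stand-in for the community structure of real
covariance networks.  An optional hub region receives correlation
`rho_hub` to every other region; spectral feasibility caps realistic
hub strengths near the square root of the background correlation, and
the default is 0.3.  Longitudinal designs draw baseline and follow-up
residuals with within-subject correlation `rho_t = 0.8` (test–retest
reliability of volumetry is high; the value is a free parameter, as no
empirical within-subject correlation is available for this design).

Group differences are implanted by perturbing group 2's correlations
involving a target region.  A uniform shift of a whole row is
spectrally impossible beyond a handful of regions (it contributes a
negative eigenvalue of about `−δ·√N`), so the default implant scope is
`"bridge"`: the target gains `δ` on its correlation with one region in
each of up to 6 *other* blocks, turning it into a cross-community
connector — exactly the kind of change betweenness centrality is
designed to detect.  `"block"` (within-block shift) and `"all"`
(whole-row, PSD-permitting) scopes exist; all scopes validate positive
semi-definiteness at construction and raise rather than repair.

The generator emulates: multivariate-normal volumes, block/hub
covariance, linear confounds, exchangeable or perturbed groups, paired
timepoints.  It does not emulate: non-Gaussian volume distributions,
site/scanner effects, spatially autocorrelated parcellation noise, or
subject motion artifacts — so passing tests demonstrate correctness of
the *pipeline*, not robustness to every property of real MRI data.

## Study sizes used in validation

Simulation-based checks are scaled so the whole suite runs on one CPU
in well under half an hour: the type-I-error study uses 40 regions, 30
subjects/group, 200 null cohorts at 200 permutations (the empirical
size of the global-clustering AUC test must lie in [0.02, 0.08]); the
implant-recovery study uses 40 regions, 300 subjects/group with the
+0.3 bridge implant on a sparser background (`rho_out = 0.05`, chosen
so the implanted connector is identifiable against diffuse background
connectivity), 50 cohorts at 300 permutations.  The recovery study's
measured power for `raw p < 0.05` sits near 0.7 under these
conditions (the feasible bridge implant is necessarily weaker than a
whole-row shift); the top-5 |AUC difference| rank criterion is met
almost always.

## Numerical choices and edge cases

* Edge counts use `round()` (banker's at .5 via numpy `rint`).
* Residualization uses `lstsq`, tolerating collinear covariates;
  constant covariates are dropped with a warning.
* Correlation matrices are symmetrized and clipped to [−1, 1] after
  `corrcoef` to absorb floating-point drift; diagonals are exactly 1.
* A zero-edge density, a density exceeding the available positive
  correlations (on observed data), zero-variance regions, fewer than 3
  subjects, and degenerate subgroup splits all raise typed errors.
* The NSS subgroup split dichotomizes at the sample mean change
  (baseline − follow-up; strictly above the mean → "decreasing"); an
  all-equal change vector is an error rather than a silent one-group
  split.

## Known limitations

* Weighted, signed, and individual-subject networks are out of scope.
* σ inside permutation loops is expensive (each replicate rewires
  `n_random` references per density); the pipeline defaults test C and
  L globally and offers σ via `include_sigma`.
* The paired permutation scheme is a design choice (see above); both
  it and the unpaired fallback are logged in run metadata.
* FDR is applied per comparison across regions; no correction is
  applied across the (few) global tests or across comparisons.
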