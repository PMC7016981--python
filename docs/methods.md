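# Methods

## Input model

The pipeline starts from a normalized log2-scale gene × sample matrix (the
kind produced by RMA summarization of expression microarrays, or any
log-transformed abundance table) plus a design table mapping each sample to
a time-point label and replicate index. Time-point labels are metadata only:
every computation treats time-points as ordered categories, so the spacing
of the sampling ages never enters the statistics. Each time-point needs at
least two replicates.

## Dynamic-gene filter

Per gene, replicate values are averaged per time-point on the log2 scale and
then exponentiated; the dispersion statistic

    chi2 = sum_i (Xi_bar − X_bar)^2 / X_bar,   df = n − 1,

is computed on the linear scale, with `X_bar` the unweighted mean of the
per-time-point means and `n` the number of time-points. The statistic is a
variance-to-mean ratio and presumes a positive, ratio-scale variable — hence
the linear scale; applying it to log2 values would change its meaning. Its
known property is scale dependence: multiplying all intensities by `c`
multiplies chi2 by `c`, so the baseline intensity of the data is part of the
test's operating point (the test suite asserts this property rather than
hiding it).

P-values (upper tail, chi-squared with `n − 1` df) are Benjamini–Hochberg
adjusted across all genes. A gene is dynamic iff adjusted p < 0.01 **and**
linear max/min fold change across time-point means > 2, both inequalities
strict — a ratio of exactly 2.0 is rejected. The per-time-point up/down
summary standardizes each dynamic gene's log2 mean profile (z-score across
time-points, ddof 1) and counts the gene as up (down) wherever the profile
exceeds +0.5 sd (falls below −0.5 sd) — the same margin used for pattern
peak calls, chosen so replicate-level wiggles do not register.

## Pattern clustering

Profiles are per-time-point means, not replicate columns, z-scored per gene
(ddof 1; zero-variance genes are dropped with a recorded reason). Fuzzy
c-means uses the standard alternating updates

    u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m−1)),
    c_j = sum_i u_ij^m x_i / sum_i u_ij^m,

with fuzzifier m = 1.25 (close to hard k-means while retaining graded
memberships), convergence when the objective changes by < 1e-6, a 1000-
iteration cap, and the best of 10 seeded restarts (centroids initialized on
random data rows) kept by final objective. A zero distance gives crisp
membership on the coincident centroid. The objective is asserted
non-increasing at every iteration.

The number of patterns is selected by scanning c ascending and keeping the
largest c for which all pairwise centroid Pearson correlations stay below
0.9 (the non-overlap criterion); the scan stops at the first violation, and
a violation already at c = 2 returns 2 with a warning flag. Genes are
assigned to their argmax cluster only when that membership reaches 0.5 — at
this threshold at most one cluster can qualify, and exact 0.5/0.5 ties go to
the lower cluster index and are recorded. Pattern taxonomy reads the
centroid in sd units: strict local extrema beyond ±0.5 sd are peaks
(plateaus are not extrema), direction follows the dominant peak's sign, one
peak is unimodal and two or more bimodal, and a centroid that never leaves
the margin is labelled flat with a warning.

## Pathway coregulation

The single-sample enrichment score ranks a sample's genes descending (ties
broken by stable input order and logged), assigns rank N to the top gene,
and accumulates the difference between the rank-weighted in-set ECDF
(weights r^alpha, alpha = 0.25) and the unweighted out-of-set ECDF over the
whole list. The score depends on ranks only, so it is invariant to monotone
transforms of the expression values. Sets are intersected with the matrix
universe at load time (dropped members logged); sets with fewer than two
members in the universe, or equal to it, error per set without stopping the
run. Per signature, a 0–1 normalized track (min→0, max→1 across samples) is
kept for display and for the per-time-point tests.

Signature tracks are Pearson-correlated over per-sample scores (18
observations in the default design) rather than time-point means — a
deliberate power choice; the 6-observation variant is available via
`on="timepoint_means"`. Two-sided p-values use the t-transform of r.
Coregulation clusters require every within-group pair to be significantly
(p < 0.05) and *positively* correlated, i.e. the group is a clique in the
significance graph; disjoint clusters come from greedy extraction (largest
maximal clique first, ties by lexicographic member order, claimed
signatures removed, repeat), and singletons are not clusters. Per cluster
and time-point, member 0–1 scores at that time-point are compared against
the member scores at all other time-points pooled with a two-sided
Mann–Whitney U test (reported as NaN when either side has fewer than three
scores), starred at 0.05/0.01/0.001. The one-vs-pooled comparison is the
simplest structure consistent with per-time-point significance stars; other
groupings are defensible.

## Coexpression networks and hubs

Networks are unsigned: A_ij = |cor(x_i, x_j)|^beta on replicate-level
columns (n = 18 in the default design), zero diagonal; zero-variance genes
get zero correlations and a flag. The soft power is the smallest integer in
1..20 whose connectivity distribution passes a scale-free topology fit of
0.8 — fit = signed R² of the log10 p(k) ~ log10 k regression over 10
equal-width bins of log10(k), negated for a positive slope — with a
conventional fallback of beta = 6 when no power qualifies. A non-positive
fit target degenerately returns the smallest power. On the synthetic
single-module patterns this fallback is the expected outcome: a module of
uniformly intercorrelated genes is deliberately *not* scale-free, and the
fallback is asserted in the tests rather than treated as a failure.

TOM_ij = (Σ_u A_iu A_uj + A_ij) / (min(k_i,k_j) + 1 − A_ij) off-diagonal and
1 on the diagonal; kWithin is the row sum of A over the pattern's members.
No module-detection step is run — each expression pattern is one module, its
member set fixed by the clustering stage. The module eigengene is the first
right singular vector of the row-standardized member matrix, sign-oriented
to correlate positively with the mean member profile; kME is each member's
Pearson correlation with it. Hubs are the top `ceil(0.10 × pattern size)`
genes by kWithin — the ceiling guarantees at least one hub — with ties
broken by higher kME and then stable id order. Hub overlap against reference
gene lists reports the observed percentage of hubs found in the union of the
lists next to the same statistic for 50 uniform same-size draws from the
universe.

## Synthetic data

The generator emulates a six-time-point, three-replicate log2 expression
matrix: a static majority at a common baseline and dynamic genes following
planted templates (relative log2 offsets per time-point, rescaled so the
largest offset equals the configured amplitude). Replicate noise is i.i.d.
Gaussian on the log2 scale (log-normal linearly), matching RMA-style
intensity behaviour; heavier-tailed noise, batch effects and missing values
are out of scope, so passing tests speak to the statistical machinery, not
to robustness against those artefacts.

Defaults, chosen once as a realistic desk-scale stand-in for a genome-wide
array study: universe 5,000 genes, baseline log2 intensity 6.0 (linear 64 —
a mid-range array intensity; because chi2 scales with the linear mean, the
baseline is part of the filter's operating point and the default gives the
null simulation its intended sub-1% false-positive behaviour), replicate
noise sd 0.25 log2, amplitude 2.0 log2 (planted fold change 2² = 4, safely
past the 2-fold rule; amplitudes ≤ 1.0 trigger a warning because planted
genes may then fail it). The six default templates are single peaks up at
the first/middle/last time-points, single dips down at two ages, and one
bimodal pattern — mutually dissimilar so the non-overlap criterion has a
well-defined answer of six.

Gene sets: `n_sets` sets of `set_size` genes; aligned sets draw
`aligned_fraction` of members from one template's genes (seeding coregulated
enrichment tracks and, with several sets on one template, a planted
coregulation clique) and fill the rest uniformly.

Hub wiring (`hub_spec`): all members of a template load on a shared
per-sample latent factor folded into the replicate noise (hubs at loading
`strength`, default 0.9; other members at half that, total noise variance
held at noise_sd²), and non-hub members additionally receive a small
per-gene temporal jitter (sd 0.3 log2, constant across replicates). The
jitter is what makes the construction decisive: hubs track the template
exactly while peripheral members wobble around it, so hubs have the highest
expected correlation with every other member and therefore the highest
expected intramodular connectivity — with shared noise alone the hub
advantage is of order 0.01 correlation units and drowns in estimation noise
at n = 18 samples. The jitter also models a real feature of coexpression
modules (core regulators track the module eigengene more tightly than
peripheral targets). It is applied only when `hub_spec` is set.

All randomness flows from the single config seed through independent named
substreams, so the matrix, gene sets and ground truth are bit-for-bit
reproducible regardless of the order the generators are called in. The
pipeline derives per-stage seeds from its one seed the same way.

## Problem sizes

The test suite and examples run the full pipeline at 2,000–5,000 genes,
six time-points × three replicates, 600 dynamic genes across six templates,
15 gene sets, and 50–500-gene pattern networks — sizes at which every
planted structure is comfortably recoverable and a full run takes seconds
to a couple of minutes on one CPU.

## Known limitations

- The chi-squared filter's scale dependence means results depend on the
  normalization of the input matrix; inputs should be on a comparable
  intensity scale to typical log2 array data.
- The non-overlap criterion compares fitted centroids only; two patterns
  with correlated centroids but distinct memberships would be merged.
- Coregulation cluster extraction is greedy; it matches exhaustive
  enumeration on small signature panels (verified to 12 signatures) but is
  not guaranteed to maximize total clustered signatures.
- The Mann–Whitney per-time-point test pools all other time-points, so a
  signature elevated at two of six ages dilutes its own contrast.
- Scale-free power selection is meaningful for large heterogeneous gene
  universes; single planted modules intentionally fall back to beta = 6.
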