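# Methods

## The model

`admixkit` infers population history from biallelic SNP allele frequencies
under a Gaussian approximation to genetic drift.  On a rooted tree, the
frequency of a SNP in a daughter population is the parent's frequency plus a
Gaussian step of variance `c * p0(1 - p0)`, where `c` is the branch's drift
parameter (roughly t/2N under pure drift) and `p0` the ancestral frequency.
A migration event is a single admixture pulse: the recipient's frequency is
`w * source + (1 - w) * parent`, with weight `w` the fraction of ancestry
contributed by the source lineage.

Under this model each tip's frequency is a linear combination of independent
per-branch drift increments, with coefficients given by the total ancestry
weight of the tip on each branch (products of `w` / `1 - w` factors over the
migration junctions on each ancestry path).  Writing those coefficients as a
matrix `U` (tips x branches) and the branch lengths as a vector `l`, the
model covariance of tip frequencies is `U diag(l) U^T`.  Because the
observed frequencies are centered per SNP by their across-population mean,
the model matrix is passed through the same double-centering projection
before being compared with data: `C = V - rowmean(V) - colmean(V) +
grandmean(V)`.

Key consequences used throughout:

* `C` is linear in branch lengths for fixed topology and weights, so the
  branch lengths maximizing the composite likelihood solve a nonnegative
  weighted least-squares problem (solved with `scipy.optimize.nnls`);
* for a migration-free tree, `C` does not depend on the root position, so
  the topology search runs unrooted and the outgroup is used only for final
  rooting.

## Observed covariance and composite likelihood

`covariance_matrix` computes, per usable SNP (every population has at least
one sampled allele), the centered frequency outer product, and averages over
SNPs.  Per-entry standard errors come from a weighted delete-one-block
jackknife over contiguous blocks of SNPs (default 20; the trailing genome
block may be short, hence the weighted form of Busing, Meijer & van der
Leeden 1999, which reduces to the textbook delete-1 formula for equal
blocks).  The per-block entry sums are kept on the object so downstream
code (migration p-values, bootstrap) can form leave-one-out estimates
without re-reading data.

By default no correction is made for finite within-population sample sizes,
mirroring the `-noss` behaviour of covariance-based admixture-graph fitting
(with small and unequal samples per population, the correction tends to
overcorrect).  With `noss=False` the binomial sampling term
`x(1-x)/(n-1)` is subtracted, propagated through the centering.

A graph is scored by a normal composite log-likelihood over the unique
matrix entries, `sum_{i<=j} log N(W[i,j]; C[i,j], SE[i,j])`.  This scale is
deliberately not comparable with TreeMix's likelihood (no Wishart /
degrees-of-freedom bookkeeping); model comparison within a run uses
likelihood differences, and cross-method comparison uses variance explained,
topologies and edge weights.

## Tree search

Searches start from neighbor joining (scikit-bio) on the drift distances
`d_ij = W_ii + W_jj - 2 W_ij`; additional searches perturb the distances
with multiplicative noise or start from random topologies (30% of restarts).
Hill-climbing proposes nearest-neighbor interchanges and, when NNI stalls,
subtree-prune-regraft moves (a bounded random subset per sweep), accepting
any likelihood improvement; branch lengths are refit by NNLS at every
proposal.  On noise-free model covariances of random 8-tip trees this
recovers the generating topology essentially always, which is the designed
sanity regime (NJ is consistent on additive distances, so the climb mostly
confirms the start).

## Migration edges

Edges are added greedily.  Each round ranks population pairs by positive
scaled residual `(W - C)/SE` — the least-squares tree fit smears an
admixture signal over several entries, so the top 4 pairs are all explored
rather than only the largest.  Candidate source/destination attachment
points lie along the two populations' root paths (up to 8 branch midpoints
per endpoint, both orientations).  Proposals are screened cheaply (weight
grid {0.05, 0.2, 0.35, 0.5} with branch lengths held fixed), the best eight
are optimized fully (bounded scalar search over `w` in [0.001, 0.999] with
NNLS refits inside), and the best five then undergo *endpoint refinement*:
the destination subtree and the source attachment are each re-placed
anywhere in the tree, keeping improvements.  Refinement is essential
because a strongly admixed population is typically misplaced by the
pure-tree search (it sits at a compromise position between its two
ancestries), so the correct structure is not reachable by attaching an edge
to the unmodified tree.

Two equally likely parameterizations exist for every admixture event: tree
parent with weight `1 - w` plus migration with weight `w`, and the mirror
with the roles swapped.  Whenever an optimized weight exceeds 0.5 the edge
is canonicalized to the majority-tree form, which keeps weights comparable
across replicates and matches the usual reporting convention.

Per-edge p-values re-estimate the weight on each leave-one-block-out
covariance with the graph structure and branch lengths fixed, and form a
weighted-jackknife Z-score (two-sided normal p).

## f-statistics

`f3(X; Y, W) = E[(x - y)(x - w)]` and `f4(X, Y; W, Z) = E[(x - y)(w - z)]`
are computed per SNP on complete cases (all argument populations have data)
and averaged; standard errors use the same genome-contiguous 20-SNP block
jackknife as the covariance machinery rather than per-statistic re-blocking.
The admixture form subtracts the apex sampling-noise term
`x(1-x)/(n_X - 1)` by default (the standard unbiased estimator); the
outgroup form leaves it off by default since only the ranking across
reference taxa is interpreted — both are toggleable.  `|Z_diff|` between two
outgroup-f3 values is computed from the per-block *paired* difference of
the per-SNP statistics on the common usable SNPs, which accounts for the
strong positive correlation between the two statistics.  p-values use
normal tails (one-sided lower for admixture f3, two-sided for f4);
familywise error over a battery of tests is controlled with Holm's
step-down procedure (statsmodels).

## LD handling

Rather than pruning SNPs, the pipeline blocks them: within-species LD decay
is estimated (pairwise genotype r² within a 500 kb window, medians in
sequential bins of 75 pairs), a distance threshold safely beyond the decay
range is chosen (200 kb by default; threshold choice is not automated), and
`determine_block_size` finds the smallest block size k (grid 5, 10, 15, …)
such that consecutive block midpoints on the same chromosome are always
farther apart than the threshold.  Block midpoints are range midpoints
`(first + last)/2` of the block part on a chromosome (a flag switches to
the mean position); blocks straddling a chromosome boundary contribute one
midpoint per chromosome.  A k so coarse that no two midpoints are
comparable does not count as satisfying the criterion.  Species enter the
LD analysis only with >= 10 accessions and >= 600 intraspecific SNPs.

## Bootstrap migration support

`MS` asks how often a full refit (tree search plus m migration edges) of a
block-bootstrap replicate of the SNP blocks contains an edge matching a
reference edge.  Strict matching requires identical origin and destination
tip-sets; the extended index `MS_E` relaxes each endpoint to non-strict
containment with orientation preserved, which rescues edges whose
attachment wanders within a clade across replicates.  Both are percentages
of converged replicates and `MS_E >= MS` by construction.  The match
predicate is pluggable.  Because the data are fixed and only blocks are
resampled, a spurious edge fitted to noise in a migration-free dataset is
resampled too — support values around 30-50% for such edges are expected
and observed; genuine strong edges reach 80-100%.

## Synthetic data

The simulator draws root frequencies (uniform on [0.05, 0.95] by default,
or beta), evolves them down the graph with the Gaussian drift steps above
(clipped to [0, 1]; the clipping fraction is reported and stays below ~5%
at the default drift scales, the regime where the Gaussian approximation is
trusted), mixes at migration junctions, and samples diploid genotypes
binomially with i.i.d. missingness.  Optional LD emulation gives SNPs
within a block a shared per-individual latent perturbation scaled by
`0.5 * sqrt(p(1-p))`, producing within-block genotype correlation of
roughly `rho/3` that vanishes across block boundaries; this is a
statistical emulation, not a genealogical one (no recombination map, no
coalescent), so LD decay is flat within blocks rather than
distance-decaying.  Positions are uniform per chromosome.

Canonical study conditions used by the validation suite:

* `balanced_tree(8, 0.02)` — f4 null calibration (5,000 SNPs, 20
  diploids/population, 20 replicates);
* `admixture_f3_scenario` — a 50/50 two-way admixture with between-parent
  drift 0.05 and post-admixture drift 0.005, plus a non-admixed control
  (4,000 SNPs);
* `six_tip_migration_scenario` — a fixed six-tip tree (internal branches
  0.02, pendants 0.03, outgroup 0.12) with one tip-to-tip migration of
  weight 0.4 (recovery) or 0.45 (bootstrap support); replicates vary the
  drift and sampling randomness, not the graph, so the weight is well
  identified (SE about 0.02 at 5,000 SNPs);
* `paper_like_scenario` — ~30 populations of 2-40 diploids on 19
  chromosomes with up to 8 weighted migration edges and 5% missingness,
  the smoke-test shape for the full pipeline.

What passing these tests does *not* show: robustness to ascertainment bias
of array SNPs, to non-Gaussian drift at extreme frequencies, to
genealogical LD, or to model violations such as continuous gene flow —
real-data behaviour on those axes is out of scope here.

## Numerical choices and edge cases

* Branch lengths are constrained nonnegative by NNLS; the two root-adjacent
  branches of a rooted pure tree are collinear after centering and their
  sum alone is identified (the optimizer splits it arbitrarily; rooting
  display splits the outgroup pendant edge in half).
* Migration weights live in [0.001, 0.999]; initialization 0.05; scalar
  optimization tolerance 1e-4.
* Likelihood ties in best-tree selection use a relative tolerance of 1e-6.
* Degenerate f-statistic inputs (identical reference populations) give a
  zero statistic with zero SE and are reported as Z = 0.
* Filters use strict inequalities (">20% missing" removes only strictly
  worse samples/SNPs; MAF exactly at the threshold is retained), samples
  are filtered before SNPs, and the anchoring filter runs first.
* The counted allele is the dataset-wide minor allele, fixed before
  stratification; all downstream statistics are invariant to consistent
  allele flips.

## Problem sizes in the validation suite

The acceptance script and test suite run at desk scale: 4,000-5,000 SNPs,
6-8 populations, 20 diploids per population, 20 data replicates per
calibration claim, 100 tree-recovery instances, 100 bootstrap replicates
for the strong-edge support index and 25 for each of the ten no-migration
repetitions.  These sizes were chosen to make each statistical claim
testable with comfortable margins while keeping the whole suite a
coffee-break run.
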