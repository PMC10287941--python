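# Methods

## Repressive tendency scoring

H3K27me3 is a repressive chromatin mark; genes kept under broad H3K27me3
domains across many cell types are disproportionately cell-identity
regulators, silenced everywhere except the lineages they define.  The
score aggregates this signal per gene from per-sample domain calls
(BED/broadPeak input; domain calling itself is out of scope):

1. **Breadth.**  For each gene and bio-sample, the breadth is the full
   length (bp) of the broadest domain overlapping the window
   `[tss − w, tss + w + 1)` with `w = 2500` by default.  `mode="total"`
   instead sums the lengths of all overlapping domains; the broadest-peak
   definition is the default because it is the one stated for the pattern
   analysis, and a single consistent definition serves both uses.
2. **Scaling.**  `a = breadth_sum / max(breadth_sum)` min-max scales the
   per-gene summed breadth to [0, 1], so RTS = a · v is itself in [0, 1]
   and thresholds are comparable across corpora.  Unscaled bp sums would
   make the published magnitude of the priority threshold (~0.01)
   impossible.
3. **Occupancy.**  Per sample, the top `ceil(0.05 · G_nonzero)` genes by
   breadth are flagged (only genes with nonzero breadth are ranked — a
   zero-breadth gene cannot carry a broad domain; ties at the cut are all
   included for determinism).  `v` is the flagged fraction over samples.

RTS is invariant to rescaling all breadths, and monotone: increasing one
gene's breadth in one sample can never lower its score.

**Priority selection.**  Genes are sorted by descending RTS (ties broken
lexicographically).  The rank curve is smoothed with a moving average
(width 1% of genes, minimum 11) and the knee is the point of maximum
perpendicular distance from the chord joining the curve's endpoints — a
standard seedless knee heuristic.  Genes strictly above the knee's RTS
form the priority set.  The procedure requires at least 100 genes with
positive RTS (a knee on a shorter curve is not meaningful); a fixed
threshold is available for small or degenerate inputs, and a flat curve
raises an error suggesting it.  The exact smoothing behind the originally
published priority-set size is unstated, so small differences in the
selected count around the transition are expected.

## Discordance score

`ds = ln(1 + x) · rts` with `x` library-size-normalised expression (each
cell scaled to the median cell total; deconvolution size factors are out
of scope).  The natural log with +1 offset keeps ds = 0 exactly for
absent genes; changing the log base rescales every ds uniformly and
cannot change any ranking.  Genes without an RTS entry get rts = 0 rather
than being dropped, so they can never rank highly but stay in the output.
Pseudo-bulk DS averages member-cell expression first and transforms the
mean profile (transform-then-average is exposed as an option); rankings
break ties lexicographically.

## Peak calling

Per cell, the priority gene with highest expression is found (ties: higher
RTS, then gene id) and its RTS becomes the cell's weight; cells expressing
no priority gene get weight 0 and simply do not contribute density.  The
weighted KDE uses an isotropic bivariate Gaussian kernel of bandwidth
`h = 0.3 · n^(−1/6)` (a Scott's-rule shape rescaled for 2D single-cell
embeddings; d = 2 throughout).  Weights are normalised to sum to one so
the field integrates to 1 — the raw `1/(nh)` prefactor does not normalise
a weighted sum, and peak calling is invariant to any positive rescaling of
the field anyway because all thresholds are relative to the maximum.  A
user-supplied bandwidth overrides the rule (published analyses sweep it;
0.3 is a typical atlas-scale choice).

Ten contour thresholds are placed linearly on (0, max cell density]
(quantile spacing available).  At each threshold DBSCAN
(`eps` = 3 × median nearest-neighbour distance of all cells,
`min_samples` = 5) clusters the cells at or above it; superlevel sets are
nested by construction.  A cluster is a **peak** when it is innermost:
among clusters with at least `min_cells` = 20 members, no qualifying
cluster at the next populated level has its majority (> 50%) of cells
inside it.  Restricting the nesting test to qualifying clusters is
deliberate: under a literal reading, a tiny (sub-`min_cells`) core at the
top level would disqualify its entire parent chain and a clear population
would yield no peak at all.  Majority containment rather than exact
subset containment absorbs DBSCAN core-point flips between levels.  Cells
in several selected peaks go to the highest-level one; cells outside
every peak stay unassigned — deliberate data trimming, the method trades
coverage for specificity.  Each peak's anchor gene is the priority gene
with highest mean expression over its members (ties: higher RTS).

Peak relationships are summarised by the Jaccard similarity of the peaks'
top-100 pseudo-bulk DS gene lists; hierarchical clustering (complete
linkage by default) runs on Euclidean distances between the rows of the
similarity matrix, with deterministic leaf order and Newick export.

## Pattern parsing

PCA of the gene × sample breadth matrix (genes are observations; samples
mean-centred, not variance-scaled) yields per-gene scores on orthogonal
deposition patterns.  The retained PC count is a required user parameter
(published analyses used ~60–70 PCs on consortium corpora; synthetic
fixtures need far fewer).

**Permutation enrichment.**  A gene is flagged *strongly associated* with
a pattern when its score exceeds the universe's 95th percentile on that
PC.  The permutation p-value draws, per permutation, a random gene set of
the input's size from the universe excluding the input set, takes the
sample's 95th percentile per PC as the null statistic (the per-permutation
maximum is available as an option), counts permutations `r` whose
statistic reaches the observed score, and reports
`p = (r + 1)/(n_perm + 1)` — bounded in `[1/(n_perm+1), 1]`, so doubling
`n_perm` halves the attainable minimum.

**Feature selection.**  The m = 10 PCs with the largest score variance
among the input genes become the GMM features.

**Model selection.**  For each candidate component count θ (1 up to
`theta_max`, capped at the list size), a diagonal-covariance Gaussian
mixture is fitted by EM with random initialisation, stopping when the
log-likelihood gain drops below 1e−3.  The default criterion is the
textbook BIC, `k_params · ln n − 2 · ln L̂` with
`k_params = θ(2d + 1) − 1`.  Two alternative penalties are exposed:
`bic_mode="total"` applies a per-cluster penalty `θ · ln n` to the total
log-likelihood, and `"mean"` applies it to the per-gene mean.  The
per-cluster variants are documented hazards rather than recommendations:
the mixture likelihood is unbounded (a component can shrink its variance
onto few points without limit), so with θ allowed to approach n the
`total` reading always favours near-degenerate high-θ fits, while the
`mean` reading over-penalises in higher dimensions and underfits.  Two
standard guards keep the scan honest under any mode: fits with a
component variance at the regularisation floor are excluded from the
argmin (the same policy mclust applies to singular fits), and EM failures
are skipped with a warning.  Because EM is init-sensitive the scan runs
10 times (seeded deterministically from one seed, default 42) and θ* is
the most frequent per-repeat argmin, ties going to the smaller θ.

**Assignment.**  A final GMM with θ* components yields per-gene
posteriors; each gene goes to its argmax-posterior cluster.  An empty
component triggers a logged refit with a new derived seed.

## Evaluation statistics

- **ARI** (permutation-model corrected, via scikit-learn) over identical
  item sets; symmetric and label-permutation invariant.
- **Gene-removal ablation.**  Gold standard: each cell labelled by its
  highest-expressed priority gene from the full list.  Genes are removed
  cumulatively in blocks of 50 — random from the priority list, bottom-up
  or top-down by RTS rank, or random from the whole universe — and the
  labelling is recomputed and compared to gold after each block.  A step
  that leaves no priority gene reports ARI = 0 with an explicit
  `total_removal` flag (never NaN); comparisons between scenarios should
  exclude such steps, where every scenario is 0 by convention.
- **Peak–peak Spearman** over pseudo-bulk profiles, full transcriptome or
  HVG subset; constant profiles give NaN with a warning.
- **HVG selection** by residual from a LOWESS mean–variance trend
  (log-variance on log-mean); an approximation of variance-model HVG
  selection, exact parity with any particular tool is a non-goal.
- **Rank-bin enrichment**: contiguous rank bins, one-tailed Fisher's
  exact test of each bin against all ranked genes.

## Synthetic data

The generators provide closed-loop ground truth; their defaults are the
conditions under which the test suite and acceptance script run.

- **Pseudo-epigenome** (default 1000 genes × 20 samples): genes on one
  synthetic chromosome (`chrS`), spaced so a TSS window plus the
  broadest possible domain cannot touch a neighbour.  Planted regulatory
  genes (default 50; 170 where knee selection or multi-step ablations are
  exercised) carry a broad domain (uniform 5–20 kb, drawn independently
  per gene and sample so top-tail flags rotate across the planted set) in
  90% of samples; background genes carry a narrow domain (0.2–1 kb) in
  50% of samples.  Under these conditions the per-sample top-5% flags
  fall exclusively on planted genes, so planted genes occupy the top RTS
  ranks exactly.
- **Atlas**: negative-binomial counts (dispersion 0.5, log-normal library
  sizes with sd 0.3, log-normal base means) with a 10-fold marker boost in
  each type's cells, plus a 2D embedding of Gaussian blobs.  Defaults:
  3 types × 250 cells, blob sd 0.4 and centre separation 4.0 —
  UMAP-like geometry where distinct populations are compact islands
  roughly one unit across separated by several units; the
  separation-to-sd ratio of 10 keeps populations unambiguous.  The
  formula bandwidth (h ≈ 0.1 at n = 750) then resolves each island as a
  single density peak; much wider blobs relative to h are visibly
  undersmoothed and can fragment, which is a real property of the method,
  not of the fixture.
- **PC clusters**: spherical unit-variance Gaussians at pairwise centre
  distance `separation` (default 8 sd) along coordinate axes in 10-D.
- **Program breadth**: a breadth matrix (1000 genes × 45 samples) with
  three disjoint sample groups; each program's 60 genes carry ~15 kb
  domains only in their group, over low exponential background.

What the fixtures do *not* emulate: dropout beyond NB sampling, doublets,
batch effects, ambient RNA, nonlinear UMAP distortions, or the continuous
differentiation topologies of real atlases.  Passing tests therefore show
that the estimators and selection rules are implemented correctly and
recover planted structure under clean conditions — not that peaks on a
real atlas are biologically complete.

## Numerical choices and limitations

- All tie-breaks (rankings, anchors, mode-across-repeats) are
  deterministic; identical inputs and seeds give bit-identical outputs.
- KDE evaluation is exact (no grid interpolation for cell densities) and
  chunked to bound memory; O(n²) in cells, comfortable to ~10⁴ cells.
- Problem sizes in the test suite and acceptance script (10³ genes,
  20–45 samples, 750 cells, 5 replicate seeds, 10 scan repeats) are the
  package's chosen synthetic study conditions; they keep full runs in the
  tens of seconds while leaving wide recovery margins.
- Peak calling depends on the embedding honouring local density — it
  consumes, never computes, the 2D coordinates.
- The knee is a geometric heuristic; on curves without a distinct regime
  change it errors rather than guessing.
- Identifier matching is exact and case-sensitive; ortholog mapping is
  the caller's responsibility.
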