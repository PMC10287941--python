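# triage-sc

Epigenetically anchored cell-population discovery and gene-program parsing
for single-cell transcriptomics.

Most single-cell clustering tools group cells purely by expression
similarity.  This package instead anchors clustering in consortium-scale
epigenomics: genes that carry **broad H3K27me3 domains** across many
cell types are strongly enriched for cell-identity regulators, and that
signal can be distilled into a per-gene **repressive tendency score (RTS)**
and used to weight, rank and interpret single-cell data.  The package is
aimed at computational biologists analysing scRNA-seq atlases who want
cell populations defined by regulatory identity rather than global
transcriptome distance.

## What it computes

**Repressive tendency score.** For gene *g* with H3K27me3 breadth
*b(g, s)* (bp of the broadest domain overlapping TSS ± 2.5 kb in
bio-sample *s*):

    RTS(g) = a(g) · v(g),
    a(g) = Σ_s b(g, s) / max_g' Σ_s b(g', s),
    v(g) = #{s : b(g, s) in top 5% of broad domains in s} / N_samples

Genes above the inflection point (knee) of the sorted RTS curve form the
*priority set*.

**Discordance score.**  DS(g, c) = ln(1 + x(g, c)) · RTS(g) for normalised
expression *x* — high DS marks genes that are expressed although usually
repressed, i.e. candidate identity regulators.

**Peak calling (`TriageCluster`).**  Each cell is weighted by the RTS of
its highest-expressed priority gene; a weighted Gaussian KDE

    f̂(x) = Σ_i ŵ_i (2πh²)⁻¹ exp(−‖x − x_i‖² / 2h²),   ŵ_i = w_i / Σw,
    h = 0.3 · n^(−1/6)

is estimated over a 2D embedding (e.g. UMAP).  Ten ascending density
thresholds are placed on the field; at each threshold DBSCAN groups the
cells above it, and the innermost clusters — those with no higher-level
cluster nested inside — are reported as *peaks*: candidate distinct cell
populations, each labelled by its *anchor gene* (the priority gene with
highest mean expression in the peak).

**Gene-list parsing (`TriageParse`).**  PCA of the gene × sample breadth
matrix extracts orthogonal H3K27me3 deposition patterns; an input gene
list (typically a peak's top-100 DS genes) is grouped in that PC space by
a diagonal-covariance Gaussian mixture whose component count θ* is chosen
by a repeated BIC scan, with per-gene permutation p-values
p = (r + 1)/(n_perm + 1) flagging strong pattern associations.

Benchmarking utilities (adjusted Rand index, gene-removal ablation
curves, peak–peak Spearman correlation, HVG selection, rank-bin Fisher
enrichment) and seed-deterministic synthetic-data generators round out
the package.

## Worked example

Simulate a pseudo-epigenome with 170 planted broad-domain genes, score
genes, simulate a 3-population atlas whose markers are top-RTS genes, and
call peaks:

```sh
triage simulate epigenome --seed 1 --n-regulatory 170 --out epi
triage rts --peaks epi --genes epi/genes.tsv --out rts.tsv
# -> 166 priority genes (threshold 0) -> rts.tsv
triage cluster --expr atlas/counts.tsv --embedding atlas/embedding.csv \
               --rts rts.tsv --out-prefix run
```

```
TRIAGE-Cluster results
======================
cells:          750
priority genes: 166
bandwidth:      0.09953
contour levels: 10 (eps=0.2066, min_samples=5)
peaks:          3 covering 120 cells

         level  n_cells         x         y anchor_gene
peak_id
peak_0       5       68 -1.180635  2.008758       g0046
peak_1       5       32 -0.928453 -1.863030       g0056
peak_2       9       20  2.480012 -0.060050       g0127
```

The three peaks are the dense cores of the three simulated populations
(cells outside any peak stay unassigned — deliberate trimming), and each
anchor gene is one of the planted markers.  The same objects are available
from Python:

```python
import triage as tg

breadth, programs = tg.simulate_program_breadth(seed=0)
genes = [g for p in range(3) for g in programs.index[programs == p][:34]][:100]
res = tg.TriageParse(genes, breadth=breadth, n_pcs=20).fit()
print(res.summary())
```

```
TRIAGE-ParseR results
=====================
genes:        100
selected PCs: PC1, PC2, PC3, PC5, PC6, PC4, PC10, PC9, PC8, PC7
theta* (BIC): 3  [per-repeat argmins: [3, 3, 3, 4, 3, 5, 3, 3, 3, 3]]
cluster sizes:
cluster
0    34
1    32
2    34
genes strongly associated with >=1 pattern: 98
```

The scan recovers the three planted deposition programs (θ\* = 3) and the
cluster sizes match the planted memberships.

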