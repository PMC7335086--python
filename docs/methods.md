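# Methods notes

## Model and procedure

`rcclust` performs divisive consensus clustering.  Each node of the
recursion is an independent, self-contained analysis of its own samples:
variance-based feature selection, per-gene z-scaling, consensus k-means
over a candidate range k = 2…maxK with maxK = min(10, ⌊N/10⌋), selection of
the best k by explicit stability criteria, and a split into the chosen
number of children.  The defining assumption is that biologically distinct
groups produce partitions that are *reproducible under subsampling*: if a
partition dissolves when 60–90% of samples and 80–100% of genes are
redrawn, it is treated as noise.  A second, independent guard requires the
partition to be transcriptionally meaningful: some cluster must upregulate
a minimum share of the selected genes at FDR < 0.01, which suppresses
stable-but-arbitrary splits of asymmetric point clouds.

Per-level feature re-selection is the reason recursion adds information
over flat clustering with a larger k: globally variant genes are dominated
by the strongest (top-level) contrasts, so sub-structure within a group is
invisible until the analysis is restricted to that group and its own
variant genes are selected.  The nested synthetic fixture reproduces this
situation by construction and the test suite asserts both halves: the
global feature set only supports the coarse split, and per-node
re-selection recovers the sub-groups.

## Statistics used for choosing k

For a consensus matrix M (index scale 0–100), the empirical CDF of the
N(N−1)/2 off-diagonal pair indices is compared with the ideal curve of a
perfectly reproducible clustering, which is flat at the between-cluster
pair fraction CDFp = 1 − [Σᵢ Nᵢ(Nᵢ−1)/2] / [N(N−1)/2] from c = 0 to 99.
All integer c whose CDF lies within ±0.5 of 100·CDFp (both axes on the
0–100 scale) are selected, a least-squares line is fitted, and while its
slope exceeds the threshold the lowest-c point is dropped and the line
refitted; a fit becomes invalid when fewer than two points remain or the
span falls under the minimum line length.  Both axes must be on the same
0–100 scale for the degree thresholds (10°, 5°) and the ±0.5 allowance to
be meaningful; on a raw [0,1] y-axis a 10° slope could never be reached.
Trimming removes the low-c end because empirical consensus CDFs rise
steeply at small indices (unstable pairs) while the plateau extends to
c = 99.

Intra-cluster stability and inter-cluster overlap are the means of
M(i,j)/100 over within- and between-cluster pairs of the consensus
partition at that k (the partition itself is average-linkage hierarchical
clustering of 1 − M/100 cut at k).  The differential-expression validity
criterion runs a two-sided Wilcoxon rank-sum test per gene, one cluster
against the rest, with Benjamini–Hochberg correction within each
comparison; a gene counts when significant (FDR < 0.01) with a positive
mean difference in at least one cluster.  The rank-sum test was chosen as
the standard nonparametric one-vs-rest test for expression data; since it
is rank-based, running it on z-scaled or log-scale values is equivalent.

A k is admissible when: line length > `min_line_length`, slope <
`min_slope_deg`, intra-stability > 0.8, inter-overlap < 0.2, and DE
fraction > `min_de_pct`.  Admissible ks receive +1 weight for slope ≤ 5°
and +1 for length ≥ 40; each of the eight subsampling processes nominates
its maximal-weight set, and the pooled most-frequent value wins the vote.
Frequency ties break toward the larger k: a coarser partition supported by
exactly the same number of processes is nested within the finer one, so the
finest equally-supported view is reported.  This matters for unequal group
sizes, where an asymmetric 2-way split can be perfectly reproducible and
tie the true k in every process; breaking toward the smaller k would
systematically report the merge instead of the groups.  The
partition realizing the voted k is taken from the nominating process whose
fitted line for that k is longest, then flattest — the most stable
evidence available.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_slope_deg` | 10° | maximum CDF line slope for admissibility (5–15° sensible) |
| `min_line_length` | 30 | minimum CDF line span, consensus-index units (30–60) |
| `min_samples` | 20 | smallest subset that will be clustered further |
| `variant_gene_pct` | 3 (bulk) / 1 (single cell) | top-variance genes kept per node |
| `bulk_min_features` | 500 | feature floor for bulk data |
| `min_de_pct` | 20 if N > 1000 else 10 | DE validity threshold, % of selected genes |
| `repeats_per_process` | 100 | consensus repeats per subsampling setting |
| `intra_stability_min` / `inter_overlap_max` | 0.8 / 0.2 | consensus-quality thresholds |
| `weight_slope_deg` / `weight_line_length` | 5° / 40 | tie-break weight thresholds |
| `marker_fdr` / `marker_lfc` | 0.01 / 1.0 | marker reporting thresholds |

## Numerical choices

- z-scaling uses the sample standard deviation (ddof = 1); variance ties in
  feature ranking break lexicographically by gene id for reproducibility.
- k-means is Lloyd's algorithm, Euclidean distance, best of 10 random
  initializations by within-cluster sum of squares, iterated to label
  convergence.  The inner loop is JIT-compiled (numba) with a pure-numpy
  fallback; both paths are deterministic given the seed.
- Two devices accelerate the engine without changing its semantics:
  clustering runs in float32, and a subsample with more features than
  samples is first replaced by an exact isometric embedding (eigenvectors
  of its centered Gram matrix scaled by root eigenvalues), which preserves
  all pairwise Euclidean distances and hence the k-means objective.
- Within one subsampling process the same per-repeat draw is clustered at
  every candidate k, so co-sampling counts are shared across k.
- The consensus index is round(100 · co-cluster / co-sampled); pairs never
  drawn together score 0.  Subsampling makes pair visibility uneven, which
  is why the ratio (not the raw co-cluster count) is used.
- Seeds: the top-level seed feeds a `numpy.random.SeedSequence`; the eight
  process seeds, the per-repeat draws and per-node child seeds all derive
  from it, making entire runs bit-reproducible.
- Degenerate draws (fewer than k distinct points) are retried and finally
  rejected; empty k-means clusters are re-seeded at the worst-fit point.
- ssGSEA: genes are ranked per sample by expression (descending, stable
  ties); the score sums the difference between the weighted (rank^0.25)
  cumulative fraction of set members and the uniform cumulative fraction of
  non-members.  Scores are z-scaled per gene set for the heatmap only.
- Survival: Kaplan–Meier per cluster with overall and pairwise log-rank
  tests (the standard KM comparison; no test is implied by a KM plot
  itself).

## Synthetic data

The generator produces group-structured log2-expression matrices: per-gene
baseline ~ Normal(5, 1), i.i.d. Normal(0, noise_sd) noise, and a disjoint
block of `markers_per_group` genes per group shifted upward by
`effect_log2` in that group only; values are clipped at 0 and an optional
dropout threshold zeroes small values.  The default scale — five groups of
50 samples, 2,000 genes, 40 markers/group, effect 3.0, noise 1.0 — gives
well-separated groups whose marker share comfortably exceeds the DE
criterion while keeping a full analysis in the tens of seconds.  The
canonical designs are five equal groups and five groups of sizes
(100, 60, 40, 30, 20).  The nested design layers a strong super-group
contrast (effect 6.0) over weaker sub-group contrasts (default effect 3.0,
the same separability as the flat design) on disjoint marker blocks;
because selection ranks by variance (∝ effect²), the global top-1% is
already fully dominated by super-group markers at this 2:1 effect ratio.
The nested demonstration runs the single-cell pipeline: it needs feature
selection to be genuinely selective, whereas the bulk 500-gene floor on a
2,000-gene matrix retains every marker block and lets the first level see
the sub-structure directly.

What the generator does *not* emulate: library-size variation, batch
effects, UMI/count noise, dropout–expression coupling, or correlated gene
modules.  Passing tests therefore demonstrate the selection and recursion
machinery under clean separable structure, not performance on real
scRNA-seq noise.

One behavior worth knowing when designing fixtures: with very few selected
features (e.g. 1% of 2,000 genes), sampling noise breaks the symmetry
between equally plausible coarse splits and a k = 2 partition can become
perfectly reproducible, tying the vote.  With a few hundred features the
coarse-split optima are near-degenerate, dissolve under subsampling and
fail the stability criteria, letting the true k win — this is the regime
the acceptance fixtures use (bulk path, 500-feature floor).

## Known limitations

- k-means is the only base clusterer (spherical-cluster bias); the engine
  is behind one interface so alternatives could be substituted.
- maxK caps at 10: data with more than 10 top-level groups need the
  recursion to find the remainder, and groups smaller than ~N/10 of their
  node can be missed at that level.
- Clusters are never re-merged across branches; a sample mis-assigned at
  level 1 cannot be recovered deeper down.
- The DE validity criterion assumes log-scale expression input; raw counts
  violate the fold-change interpretation.
- P-values from the marker tests are not corrected across levels of the
  tree, only within each one-vs-rest comparison.
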