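# Methods

This note documents the model, the numerical choices, and the synthetic
data the package is validated on, including the design decisions that were
genuinely open and why they were resolved as they were.

## Model and assumptions

The method assumes the samples of an expression matrix lie at unknown
points along a common biological progression, and that the progression is
reflected in the *gradual* change of some gene modules.  It makes no
parametric assumption about the shape of those changes; the only geometric
assumption is that consecutive stages of the process are closer in module
expression space than non-consecutive ones, which is what lets a minimum
spanning tree recover the arrangement.  Processes that drift away from a
state and return (the cell cycle) are explicitly in scope: concordance
scores only whether tree-connected samples are close, never whether
unconnected samples are far, so a trajectory that closes on itself is not
penalized.

The progression may branch.  A module whose expression is informative about
one lineage but flat elsewhere still contributes distance along that
lineage; the overall MST over the union of selected modules' genes is where
branch structure becomes resolvable.

## Pipeline parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| `kmeans_runs` | 50 | runs per consensus split | enough restarts that the consensus bipartition is stable across seeds |
| `coherence_threshold` | 0.9 | mean gene–center Pearson r | see below |
| `merge_threshold` | 0.9 | center–center Pearson r | modules correlating above this are redundant descriptions of one pattern |
| `min_module_size` | 5 | genes | smaller modules give noisy distance matrices; typical of published module analyses |
| `n_permutations` | 1000 | permutations per test | canonical value; resolution limit p = 1/1001 |
| `p_threshold` | 0.002 | permutation p | canonical value; attainable only by statistics beating ≥999 of 1000 permutations |
| `top_n_variance_genes` | all | genes | variance pre-filtering is the user's choice; the pipeline does not silently drop genes |
| `seed` | 0 | — | root of every per-stage stream |

**Coherence threshold.** The obvious-looking range around 0.7 is unusable:
a balanced mixture of two *uncorrelated* coherent patterns has coherence
√½ ≈ 0.707, so a threshold at or below that accepts clusters that are two
modules glued together, and empirically clusters in the 0.7–0.9 band are
usually a genuine module plus a minority of unrelated genes whose weak
correlation drags the mean down — exactly the genes that later corrupt the
module's distance matrix.  At 0.9 a retained module explains on average
ρ² ≈ 0.8 of each member's variance, which separates genuine modules
(coherence ≳ 0.92 at realistic noise) from contaminated ones, and sits
symmetric with the merge threshold.  Users analyzing noisier data should
lower it consciously rather than inherit a permissive default.

**Seeding.** Every stochastic stage (consensus splits, MST tie-breaking,
permutations, tree sampling, bootstrap subsampling) derives a child seed
from the root seed and a stage label (CRC32 mix, kept below 2³¹), so runs
are bit-reproducible and stages are independently re-runnable.  The
bootstrap holds the *pipeline* seed fixed across iterations and varies only
the subsampling stream, so a gene fraction of 1.0 reproduces a single
deterministic result — resampling variance is isolated by construction.

## Numerical choices

- **Standardization.** Each gene row is z-scored across samples before
  clustering and before any distance computation.  k-means with a Euclidean
  metric on raw intensities would be magnitude-dominated, while coherence is
  scale-free; z-scoring makes the two consistent.  Constant rows become
  zero vectors and are effectively uninformative; clusters consisting only
  of constant genes go to the unassigned pool.
- **Consensus splits.** The per-run 0/1 labels are clustered as vectors in
  runs-dimensional space.  A global 0↔1 flip of one run's column is a rigid
  transformation, so no label alignment across runs is needed.  All
  restarts of one split run as a single vectorised batch of Lloyd
  iterations (scikit-learn's k-means keeps only the best of n_init restarts
  and cannot return the per-run labelings the consensus needs).  Empty
  clusters are re-seeded at the point farthest from the surviving centroid.
- **MST construction.** The tree is grown from the smallest component
  (ties broken uniformly by the seeded generator) by adding the smallest
  single-linkage edge to any other component, with distance ties broken by
  the smallest index pair.  This grow-from-smallest scheme yields the
  minimum total weight; tests verify exact agreement with independent
  Kruskal and Prim implementations.
- **Permutation p-values.** p = (1 + #{permuted statistic < observed}) /
  (1 + n_perm): add-one smoothing avoids p = 0 while keeping the 0.002
  threshold attainable (1/1001 and 2/1001 qualify); the comparison is
  strict `<` so permutation-invariant statistics give p = 1.  A module
  whose off-diagonal distances are all equal cannot be ranked and returns
  p = 1 with a warning.  A module is concordant with its own MST by
  construction; the test result is still recorded.  No multiple-testing
  correction is applied across the m² tests, matching the fixed-threshold
  convention; Benjamini–Hochberg is available as a knob in the annotation
  module only.
- **Similarity reordering and block selection.** Columns of the similarity
  matrix are reordered by average-linkage hierarchical clustering
  (Euclidean), a stable standard for heatmap seriation.  Manual block
  selection is canonical.  The advisory heuristic scores every contiguous
  reordered block by size × mean off-diagonal entry: the diagonal is
  excluded because self-concordance would inflate small blocks, and the
  mean is used rather than the minimum so one marginal pair does not veto
  an otherwise uniformly high block.  Its output is labeled advisory in all
  artifacts.
- **TOM distance.** The unweighted, unsigned, one-step topological overlap
  with L1 aggregation over unordered pairs.  The aggregation is a declared
  package choice — other definitions exist and give different scales, so
  absolute TOM values should only be compared within one definition.  The
  measure is a pseudometric: distance 0 iff identical adjacency, symmetric,
  and empirically triangle-inequality-consistent.
- **Degenerate inputs.** Single-sample trees are representable but rejected
  by downstream operations; pure-noise selections produce a valid tree with
  a low-confidence warning; bootstrap iterations that fail are recorded as
  missing rather than fatal.

## Synthetic data

The generator plants a known arrangement (path or 3+-armed star) and gene
modules whose mean expression changes along it, plus i.i.d. Gaussian noise
genes; sample columns are emitted in random order, so the pipeline can
never read the arrangement from column position.

- **Path curves**: monotone ramps (alternating direction, varied
  steepness), unimodal bumps (spread centers), or sinusoids covering ¾ of
  a period with module-specific phases.  A full period would make the first
  and last samples coincide in module space; ¾ keeps the endpoints the
  best-separated pair so the planted path is the true MST.
- **Star curves**: every module changes along every arm with arm-specific
  signed rates — sign patterns cycle the six non-constant ±-patterns over
  three arms so each arm pair is sign-contrasted in two thirds of modules —
  times a concave depth ramp (early commitment).  The contrast guarantees
  same-depth samples on different arms are farther apart than consecutive
  samples within an arm, making the planted star the true MST.
- **Per-gene dispersion**: member genes carry a positive loading
  (Uniform(0.5, 1.5)) and a per-gene shift of the module curve (phase sd
  0.3 rad for sinusoids; per-arm rate jitter sd 0.3 for star modules).
  This is not cosmetic: a module whose genes are exact multiples of one
  curve is rank one, and a rank-one module's own MST is a 1-D chain that
  folds the progression wherever the curve repeats a value, breaking the
  mutual concordance the method depends on.  Real co-expressed genes peak
  at slightly different times and respond with lineage-specific strengths,
  which is exactly the dispersion modeled.

Validation conditions (also used by `scripts/acceptance.py`): the linear
benchmark is 17 samples, 9 phase-shifted sinusoid modules of 12 genes and
60% noise genes at noise sd 0.1; the branched benchmark is a root plus
3 arms of 6 samples, 6 modules of 20 genes (a typical
coherent-module size in module-based expression analyses) and 60 noise genes at sd 0.1; the
feature-selection benchmark is 4 modules of 10 genes against 300 noise
genes; the bootstrap benchmark is the linear generator at zero noise.
Problem sizes were chosen so the whole suite runs in a few minutes on one
CPU.

**What passing these benchmarks does and does not show.**  The generator
emulates gradual module-level change with Gaussian measurement noise and a
majority of uninformative genes.  It does not emulate probe effects, batch
structure, count noise of RNA-seq, correlated noise between genes, or
modules that track a confounder rather than the progression.  Recovery on
planted data therefore demonstrates the pipeline's internal correctness and
its feature-selection value under dominant noise, not performance on any
particular real dataset.

## Known limitations

- Trees cannot represent cycles: a closed trajectory is reported as a path
  with the break at its widest expression gap.
- Concordance has limited power below ~12 samples: with 1000 permutations
  and the 0.002 threshold, only statistics beating essentially every
  permutation qualify, and at small n the permutation space is too coarse.
- Automatic block selection is heuristic; heterogeneous similarity matrices
  deserve manual inspection, which the two-phase CLI run is built around.
- Absolute TOM distances depend on the declared aggregation and should not
  be compared against values computed under other TOM variants.
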