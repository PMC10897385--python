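# Methods

## The exact co-occurrence model

The unit of evidence is a binary site × entity presence–absence matrix.
Sites are Visium spots or, for FISH data, kNN cellular neighborhoods;
entities are cell types or genes. Conditional on the two presence counts
$N_1$ and $N_2$ out of $N$ sites, the joint-presence count under random,
exchangeable placement is hypergeometric (see README for the formula), and
both tail probabilities are computed exactly — no distributional
approximation, no test statistic. Tails are **inclusive of the observed
value** ($P_{lt} = P(J \le j_{obs})$, $P_{gt} = P(J \ge j_{obs})$),
following the ecology formulation this model descends from; the two tails
therefore overlap at the observed value and satisfy
$P_{lt} + P_{gt} = 1 + P_{j_{obs}}$. This convention matters: an exclusive
upper tail would flip borderline classifications.

Classification at level α (default 0.05): positive if $P_{gt} \le α$,
negative if $P_{lt} \le α$, else random. In degenerate tiny cases both
tails can fall below α; the smaller tail then wins and an exact tie is
random. Entities present at zero or all sites are reported as random with
a `degenerate` flag, never dropped. Probabilities are evaluated through
scipy's log-gamma-based hypergeometric functions and are stable for
$N \ge 10^5$.

Because the test conditions on $(N, N_1, N_2)$, classification is
independent of abundance: scaling both marginals while the observed count
tracks its null expectation $N_1 N_2 / N$ leaves the call random. This is
the property that distinguishes co-occurrence analysis from differential
expression or abundance testing.

Multiple testing uses Benjamini–Hochberg separately on the $P_{gt}$ and
$P_{lt}$ columns of each table. Raw p and adjusted q are always both
reported, since whether a given analysis should gate on p or q is a
judgment the caller owns (cell-type tables are often read at raw p, LR
tables at FDR). The ecology convention of discarding pairs with expected
co-occurrence below 1 is available (`expected_min`, plus
`apply_expected_filter` to exclude them from the FDR set) but off by
default; such pairs are flagged, not removed.

## Composition classes

Deconvolution (SPOTlight / RCTD / STdeconvolve-like tools, run upstream)
yields per-spot cell-type identity probabilities. Cell-type presence is
$P > 0.1$, **strict**: 0.10 is absence, 0.11 presence. Spots are clustered
into composition classes by k-means on the raw probability matrix with
`n_restarts` (default 25) initializations, keeping the best
within-cluster sum of squares; the number of classes is a user decision
supported by an elbow/silhouette report (tissues differ; no automatic k).
Clustering the raw matrix rather than a 2-D embedding was a deliberate
choice: it is deterministic given a seed and avoids embedding
stochasticity; `on_embedding=True` (PCA) is available for comparison.
Class labels are renumbered 1..k by decreasing size purely for cross-run
comparability — the numbering carries no biological meaning, and
label-partition content is invariant to spot order for well-separated
data. Degenerate input (all rows identical) raises rather than returning
an arbitrary partition.

## Ligand–receptor analysis

Gene presence is count ≥ `min_count` with default 1, which makes the test
agnostic to expression level. (The threshold is exposed because reasonable
analyses may want ≥ 2 to exclude single-molecule noise; a stricter "count
> 1" reading of the rule corresponds to `min_count=2`.) Co-occurrence of
annotated LR pairs, or of all ligand × receptor combinations
("surfaceome" mode, self-pairs excluded, annotated pairs flagged), is
computed within one site stratum — a composition class or a condition —
with BH-FDR over the tested pairs of that stratum. Pairs whose genes are
absent from the matrix are skipped and listed in `skipped_pairs`, not
silently treated as q = 1.

Spearman correlation of raw ligand and receptor counts across the same
sites (double zeros included; `nonzero_only=True` restricts to sites
expressing either gene) ranks the positively co-occurring pairs; rho is
NaN when either gene is constant. Output orders significant pairs first by
descending rho.

Differential co-occurrence between a target and a reference stratum
selects pairs with $q_{target} < 0.05$ and $q_{other} > 0.05$ and scores
them $q_{other} - q_{target}$, so selected pairs score positive. Both q
values are retained, making the opposite sign convention recoverable. The
two tables are outer-joined; a pair missing on one side gets q = 1 there
with an explicit flag (disjoint universes are an error under `strict`).

## LR-associated signatures

Within one composition class, spots double positive (both LR genes
present) and double negative (neither) are contrasted per gene with the
two-sided Wilcoxon rank-sum test; single-positive spots are excluded.
Small groups (both ≤ 25) use the exact null distribution (shift
algorithm, not tie-corrected — conservative under heavy ties), larger
groups the tie-corrected continuity-corrected normal approximation. Genes
with zero counts everywhere are skipped; both groups must have ≥ 3 spots.
Counts are log-CPM normalized per spot before testing by default, because
the DP/DN split can correlate with library size; `normalization="none"`
tests raw counts. The log2 fold change is computed on raw count means with
pseudocount 1.

Specificity is assessed against a permutation null: B (default 1000)
random re-splits of the same spots into groups of the observed sizes, with
per-gene p-values recomputed each round by a vectorized tie-corrected
normal-approximation rank-sum (unit-tested against scipy). Each gene's
Monte Carlo p is the add-one fraction $(1 + \#\{p_{null} \le
p_{obs}\})/(B+1)$ — per gene against its own null by default, with a
`pooled` mode comparing against all genes' null p-values, since which of
the two the original formulation intended is not determinable. The add-one
estimator avoids zero p-values; the smallest achievable value is
$1/(B+1)$. BH across genes' Monte Carlo p-values gives the Monte Carlo
FDR. When the permuted sites are exactly the union of the two groups,
ranks are computed once and only re-summed per permutation, making
B = 1000 on 500 genes a sub-second operation.

## kNN neighborhoods (FISH data)

Segments with fewer than 3 molecules or fewer than 3 detected genes are
removed (a segment with exactly 3 molecules over 3 genes is retained).
Annotation assigns each segment the cell type whose marker genes sum to
the highest count; ties and all-zero scores yield "unassigned", which is
never an entity in downstream tests. Neighborhoods are the focal cell plus
its k = 5 nearest neighbors by Euclidean distance in the input coordinate
units (no unit conversion is performed). The focal cell is included by
default — its own type is biologically part of its neighborhood — with
`include_focal=False` available, since formulations differ on this point.
Distances are computed brute-force in chunks with a deterministic
(distance, segment id) tie-break; kd-tree libraries do not guarantee tie
order. ROIs with ≤ k segments collapse to a single flagged neighborhood.
Each ROI is analyzed separately (a pooled mode exists for power studies
only). Note a structural feature of the null: because every cell carries
exactly one label, types compete for the k + 1 slots of a neighborhood,
which biases independent pairs slightly toward negative — never toward
positive, so positive calls remain conservative.

## Synthetic data

The generators produce every input the pipeline consumes, with planted
truth returned alongside:

- **Deconvolution matrices**: spots pick one of 3 archetypal composition
  profiles uniformly and draw probabilities from
  Dirichlet(30 × profile) — tight, well-separated communities typical of
  layered tissue. Planted co-occurring cell-type pairs are realized
  directly on the presence scale with an exact four-cell joint law
  (both / A only / B only / neither), presence mapped above the 0.1
  threshold (uniform 0.12–0.35) and absence below (0–0.08), remaining
  columns rescaled so rows still sum to 1. This rescaling makes background
  types compete for probability mass — background pairs can classify
  negative, a compositional artifact to keep in mind when reading
  synthetic tables.
- **Count matrices**: negative binomial with log-normal gene means
  (log-mean 1, log-sd 1) and log-normal library factors (log-sd 0.3).
  Gene-wise dispersion follows the standard decreasing dispersion–mean
  trend `0.1 + slope/mean`, slope calibrated so a typical gene has
  dispersion 0.5; a flat high dispersion at all expression levels would
  be both unrealistic and make moderate fold changes undetectable at any
  expression level. Planted LR pairs get joint Bernoulli presence per
  stratum and counts 1 + Poisson(3 × shared log-normal amplitude) when
  present, giving the correlated ligand/receptor expression an interacting
  pair should show. Planted DE genes are moderately highly expressed
  (mean 20) with a 2-fold mean shift in double-positive spots.
- **Point patterns**: per ROI, cells uniform in a 500 µm window with
  types i.i.d. (null), the second pair member placed at a Gaussian offset
  (15 µm bandwidth) from a random first-member cell (co-localized), or
  the two types confined to opposite window halves (segregated). Marker
  counts (1 + Poisson(1) on each of the type's three markers, Poisson(0.05)
  background) pass QC and make annotation recover truth.

All generators are deterministic given an integer seed.

### What the simulations do and do not show

The generators reproduce the statistical structure the analysis assumes —
exchangeable sites within a stratum, presence-level planted association,
NB-distributed counts — but not several features of real data: spatial
autocorrelation between neighboring spots, hexagonal spot geometry,
segmentation errors, batch effects, or deconvolution uncertainty
(probabilities are taken at face value). Passing tests therefore
demonstrate correctness and calibration of the inference given its inputs,
not robustness to upstream artifacts; batch correction and careful
deconvolution remain the caller's responsibility.

## Numerical and design notes

- All tail probabilities are clipped to [0, 1]; distributions are computed
  per-term in log space and exponentiated.
- Co-occurrence tables have a fixed, documented column order and
  round-trip through CSV bit-exactly (floats written at full repr
  precision); output row order is lexicographic in the entity pair.
- Problem sizes in the test-suite simulations (e.g. N = 500 sites,
  100,000 shuffles, 200 replicates, B = 500 permutations, 500 genes at 40
  spots per group) were chosen to give the asserted rates comfortable
  Monte Carlo margins while keeping the suite fast on a single CPU.
- Known limitations: the model treats sites as exchangeable within a
  stratum and is deliberately not a spatially explicit null (no
  distance-restricted permutations); overlapping kNN neighborhoods are
  correlated sites, which the per-ROI hypergeometric test does not model —
  empirically its positive-call rate stays below nominal α (the label
  competition noted above). Gene symbols are opaque case-sensitive
  strings; merging case-folded duplicates is an upstream curation
  decision.
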