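# Methods

## Model and assumptions

`cernet` builds a lncRNA-mediated ceRNA network in two filtering stages and
then characterizes it.

**Stage 1 — shared-miRNA significance.** The null model treats the miRNA
sets of a lncRNA (size N) and an mRNA (size M) as independent uniform draws
from a universe of K miRNAs, so the shared count is hypergeometric with mean
M·N/K. The pair's p-value is the upper tail P(X ≥ Y). Two tail conventions
are provided:

* `inclusive` (default): P(X ≥ Y), the conventional one-sided test;
* `strict`: P(X > Y). Some typeset presentations of this test write
  1 − Σ_{t=0}^{Y}, which excludes the observed count; under it a pair whose
  overlap equals min(M, N) gets p = 0 regardless of K. We keep the strict
  form available for comparability but default to the inclusive tail.

K defaults to the size of the catalog's miRNA universe (the union of all
miRNA ids in both interaction tables) and can be overridden when the
relevant universe is known to be larger (e.g. all annotated miRNAs of the
genome). Only pairs sharing at least `min_shared = 1` miRNA are tested;
zero-overlap pairs can never be called significant and including them only
inflates the multiple-testing burden. BH adjustment is applied jointly over
all tested pairs, and q < 0.01 (strict) is the default cutoff.
lncRNA–lncRNA testing is off by default but available, since competing
modules may contain lncRNA partners.

**Stage 2 — co-expression weight.** Candidate pairs are weighted from
Pearson correlations of their expression vectors. Two definitions exist
because the field uses both:

* `pooled_abs` — |PCC over all samples|, bounded by 1;
* `group_difference` (default) — |PCC_tumor − PCC_normal|, bounded by 2.
  Only this definition can exceed 1, which happens exactly when the two
  groups correlate with opposite signs; reported LMCN weight ranges with
  maxima above 1 are only consistent with this definition, which is why it
  is the default.

The cutoff (default 0.8) is strict: ties at exactly 0.8 are excluded. The
pooled PCC uses both groups' samples concatenated; per-group PCCs use only
that group's samples.

**Topology.** Centralities are computed on the unweighted topology (weights
are annotations only): degree; Freeman shortest-path betweenness in
pair-count form (each unordered pair counted once; optional normalization by
(n−1)(n−2)/2); closeness restricted to a node's connected component,
(number of reachable nodes) / (sum of distances to them), so values are
comparable within components of a possibly disconnected LMCN. Hubs are
nodes with degree strictly greater than the threshold (default 60). The
scale-free check fits log10(frequency) on log10(degree) by OLS over degrees
with nonzero frequency — the histogram-R² statistic customary in this
literature, chosen over maximum-likelihood exponent estimation for
comparability with reported R² values. Class comparison uses the Welch
(unequal-variance) two-sample t-test; when both classes have zero variance
the degenerate case returns t = 0, p = 1 for equal means.

**Modules.** Maximal bicliques are enumerated exactly with Close-by-One
(CbO) over the lncRNA side: every maximal biclique (A, B) is a closed
concept of the bipartite adjacency (A = {l : adj(l) ⊇ B},
B = ∩_{l∈A} adj(l)), and CbO visits each concept once via a canonicity
test. Cost is proportional to the number of concepts, which is small for
the sparse, star-like networks this stage receives; exactness was preferred
over heuristic mining because no approximation is needed at this scale.
lncRNA–lncRNA edges are accommodated by mirroring each lncRNA partner onto
the partner side as a tagged copy; a consequence is that a module built on
lncRNA partners can also appear with the two roles exchanged — both are
genuine maximal bicliques of the mirrored graph and both are reported.
Minimum side sizes default to 2×2 (1×k bicliques are ordinary stars);
selection keeps the top-k modules by gene count with ties broken by the
sorted member tuple, making the ranking explicit and deterministic.

**Enrichment and qPCR.** Gene-set enrichment is the one-sided Fisher exact
test — the same hypergeometric tail as stage 1, from one shared
implementation — with annotations intersected with the background before
testing and BH applied within each collection (conventional cutoffs:
FDR < 0.01 for GO-style collections, < 0.05 for pathway collections; one
cutoff per `enrich()` call). The background defaults to all mRNAs of the
input expression matrix. This is plain Fisher, not the modified
one-tailed EASE score some annotation servers apply; results from such
servers will differ accordingly. Fold change follows
ΔΔCt = (Ct_target − Ct_ref)_case − (Ct_target − Ct_ref)_control and
2^(−ΔΔCt), so down-regulation (positive ΔΔCt) gives fold change < 1.

## Numerical choices

* Hypergeometric tails are summed in exact integer arithmetic for K ≤ 2000
  (the result is correct to full double precision; converting the final
  rational through `Fraction` is correctly rounded) and in log space via
  scipy's survival function for larger K. Results are clipped to [0, 1].
* BH adjustment delegates to statsmodels' step-up implementation after
  validating the input range; outputs return in input order.
* Pearson correlation requires length ≥ 3 and nonzero variance; rows
  constant within either sample group are dropped when the expression
  matrix is constructed (with a logged warning), so downstream correlations
  are always defined.
* All writers emit rows in deterministic sorted order with `%.17g` float
  formatting, and readers parse with round-trip float precision, so
  write→read is lossless and repeated runs are byte-identical.
* Duplicate edges with conflicting weights, ids claimed by both RNA
  classes, and miRNAs outside the declared universe are hard errors rather
  than silent merges.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, not
any particular platform:

* **Catalog.** Background miRNA sets are uniform draws of size 5–15 from a
  K = 500 universe (null overlap expectation M·N/K ≈ 0.2, matching a regime
  where ≥ 5 shared miRNAs is strong evidence). Planted pairs are built by
  exact set construction — core of `shared` miRNAs plus disjoint private
  miRNAs — so Y is deterministic and the test's inputs are controllable.
* **Expression.** 20 samples per group by default (the case/control design
  the pipeline targets), unit-variance Gaussian noise scaled by `noise_sd`.
  Planted pairs follow a per-group latent factor x = √ρ·z + √(1−ρ)·ε with
  the sign of ρ carried on one loading, so within-group sample PCC
  converges to ρ_tumor and ρ_normal respectively.
* **Modules.** Every member of a planted module receives the module's
  miRNA core (8 by default) plus private miRNAs, and loads a common
  per-group factor (ρ = 0.99 in tumor, 0 in normal by default). Module
  scenarios default to 500 samples per group: the weight filter needs
  |PCC_tumor − PCC_normal| > 0.8 on *every* cross edge, and the null-group
  PCC has sampling SD ≈ 1/√(n−3), so n = 500 makes simultaneous recovery of
  ~100 cross edges reliable whereas n = 20 would not be. Genes may not be
  shared between planted structures — a shared gene would silently
  overwrite the earlier construction, so it is rejected.
* One integer seed drives everything; per-stage generators derive from it
  by fixed offsets, making whole datasets bit-stable.

What the generator does **not** emulate: count-based noise models,
normalization artifacts, probe-level effects, miRNA expression, or
correlated backgrounds. Passing tests therefore demonstrate the pipeline's
statistical behavior under its own model assumptions, not performance on
any specific real platform.

## Problem sizes used in validation

The validation suite runs 200 pure-null datasets (type-I control), 100
planted-pair datasets of 5 pairs each (sensitivity/precision), exhaustive
hypergeometric checks for all K ≤ 60, brute-force centrality comparison on
200 random graphs of ≤ 12 nodes, biclique-oracle comparison on 30 random
bipartite graphs, and 20 paired preferential-attachment vs uniform-random
graphs of 2000 nodes; the acceptance script scales the simulation studies
to 50 planted and 100 null datasets. These sizes were chosen so Monte-Carlo
error is small relative to the asserted margins.

## Known limitations

* The hypergeometric null assumes miRNA sets are uniform random draws;
  real miRNA–target catalogs are heavy-tailed, which the generator's
  uniform background does not reproduce.
* The group-difference weight mixes correlation sign changes and magnitude
  changes into one scalar; pairs gaining correlation and pairs flipping
  sign are not distinguished.
* Biclique mirror duplicates (see Modules) may both survive size selection
  on networks rich in lncRNA–lncRNA edges.
* The OLS histogram fit is a comparability statistic, not a rigorous test
  of power-law behavior.
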