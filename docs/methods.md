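# Methods

## Scope and pipeline

`loctom` implements a preprocessing-plus-clustering pipeline for protein
interaction networks (PINs):

1. **Co-localization filtering.** A global PIN (GPIN) is restricted to
   edges whose endpoints share at least one major subcellular location,
   yielding the co-localization PIN (CLPIN). Edges with an unannotated
   endpoint are removed, and nodes left isolated are dropped by default, so
   the CLPIN shrinks in both interactions and proteins.
2. **Overlap scoring and imputation.** Pairwise topological overlap (TOM)
   or its location-gated variant (LTOM) is computed for all pairs;
   non-adjacent pairs scoring at or above τ are added as imputed edges.
   No new proteins are ever recruited.
3. **Module detection.** Greedy cohesiveness growth (ClusterONE-style) or
   Markov clustering, followed by size/density filtering.
4. **Evaluation and enrichment.** Clustering-wise Sn/PPV/Acc against a
   reference complex catalog; per-module hypergeometric gene-set tests with
   BH-FDR and the module-set-level overrepresentation score (ORS).

## Location annotation

Raw compartment labels are merged to six major locations: nucleus,
cytoplasm, membrane, extracellular, mitochondria, and secretory-pathway
(the latter absorbing Golgi apparatus, endoplasmic reticulum, endosome,
peroxisome, lysosome, vacuole and vesicles). The merge map ships as YAML
data, not code, so alternative compartment schemes can be supplied.
Mitochondria is kept as its own major location; compartment taxonomies
differ on whether it belongs to the secretory route, and keeping it
separate preserves the six-location scheme the rest of the defaults assume.
Major labels map to themselves, making the merge idempotent. Unknown
labels are rejected by default; a lenient mode drops them with a logged
count, because silently losing annotation would corrupt the
co-localization filter downstream.

## Overlap models

With binary adjacency `a_ij` (zero diagonal) and degrees `K_i`:

```
TOM(i,j)  = ( Σ_{u∉{i,j}} a_iu a_uj + a_ij ) / ( min(K_i,K_j) + 1 − a_ij )
LTOM(i,j) = ( Σ_{u∉{i,j}} a_iu a_uj σ(i,u,j) + a_ij σ′(i,j) ) / ( min(K_i,K_j) + 1 − a_ij )
```

* The numerator sum excludes `u ∈ {i,j}`; the direct edge enters exactly
  once. A matrix-product formulation with unit diagonal would count `a_ij`
  twice for adjacent pairs, so the implementation keeps the adjacency
  diagonal at zero, making the plain matrix square realize the
  `u ∉ {i,j}` convention exactly. Brute-force double-loop oracles in the
  test suite are the ground truth for both models.
* The denominator is always ≥ 1 (asserted), the diagonal is defined as 1,
  and all entries lie in `[0,1]` (validated on construction).
* `σ(i,u,j)` is 1 iff a location is common to all three proteins;
  `σ′(i,j) = σ(i,i,j)`. Gating can only remove numerator terms, hence
  `LTOM ≤ TOM` pointwise, with equality when all proteins share a location.
* Unannotated nodes in lenient mode carry an empty location set, closing
  every gate that involves them: co-localization is never fabricated.
* LTOM is computed by grouping pairs on their common-location bitmask
  (≤ 2⁶ distinct masks over six locations), turning the gated
  shared-partner count into a handful of dense matrix products. The dense
  contract is the definition; results match the brute-force oracle to
  1e-12.

## Imputation threshold

How overlap scores become edges is a genuinely open design point: the
upstream description implies a selective rule without stating one. The
package makes it explicit and reproducible: a threshold τ ∈ (0,1], default
0.5, adding all non-adjacent pairs with score ≥ τ (original edges are kept);
an alternative top-k mode adds the k best-scoring non-edges for users who
need to hit a target edge count. τ ≤ 0 is rejected — it would add every
pair sharing any neighbor.

## Module detection

**Greedy cohesiveness.** `f(V) = w_in / (w_in + w_bound + p·|V|)`, where
`w_in` counts edges inside `V`, `w_bound` edges crossing its boundary, and
`p·|V|` (default p = 2, the published ClusterONE default; the value used in
the original study is not stated) penalizes small sets to model missing
interactions. The detector is a documented simplification of ClusterONE:
seeds are all nodes not yet covered, processed in descending degree with
lexicographic tie-break; each step applies the single vertex addition or
removal with the largest strict cohesiveness gain; growth stops at a local
maximum; clusters with overlap score `ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8` are
merged to a fixed point. Determinism follows from the fixed seed order and
tie-breaks. Exact agreement with the ClusterONE binary (its seed selection,
significance filter, p-value ordering) is a non-goal; the acceptance
surface is cohesiveness correctness and planted-module recovery.

**MCL.** Expansion (matrix squaring) alternates with inflation (entrywise
power 2.0 + column renormalization) on the self-loop-augmented,
column-stochastic walk matrix until the maximum entry change falls below
1e-6 (at most 100 iterations; non-convergence warns and returns the current
structure). Entries below 1e-8 are pruned after each inflation for
tractability — this can change clusters on pathological inputs. Hard
clusters are the connected components of the limit matrix's support;
singleton clusters are discarded. Column sums are asserted to stay within
1e-9 of 1 at every iteration.

**Filtering.** Detected clusters are reported as modules when size ≥ 10
and internal density ≥ 0.25 (both inclusive, matching the tabulated
"size ≥" convention over the loose prose "larger than"); both bounds are
parameters.

## Evaluation

From the overlap table `t_ij = |predicted_i ∩ reference_j|`:

```
Sn  = Σ_j max_i t_ij / Σ_j w_j        with w_j = |reference_j|
PPV = Σ_i max_j t_ij / Σ_i Σ_j t_ij   (0 when the denominator is 0)
Acc = √(Sn·PPV)
```

The weight `w_j` is adopted as the reference complex size — the standard
clustering-wise sensitivity (Brohée & van Helden), which keeps Sn in
[0,1]. Reference complexes are *not* restricted to proteins present in the
predicted network; that conservative choice can only lower Sn. Report
output rounds to 4 decimal places.

Edge-level predictions against labeled positive/negative interaction sets
get tp/fp/tn/fn, precision, recall and Matthews correlation (MCC defined
as 0 when any confusion-matrix marginal is 0); the labeled sets must be
disjoint.

## Enrichment

Each module of size n from a background of N proteins is tested against a
gene set of size T via the upper-tail hypergeometric probability
P(X ≥ t), computed by `scipy.stats.hypergeom.sf` (log-space stable for
large N). The background defaults to the analyzed network's protein set —
genes outside it cannot be drawn into any module — with an integer
override for other universes. Raw p-values are BH-adjusted
(`statsmodels` step-up); significance is strict, `p_adj < cutoff`
(default 0.01). ORS is the significant fraction of modules. Because the
ratio of "gene-set members found in significant modules" can sensibly be
reported against either the full gene set or only its network-annotated
part, both denominators are exposed
(`cancer_gene_ratio`, `cancer_gene_ratio_annotated`). Overlapping modules
never double-count a gene: the union of members is taken first.

## Network statistics

Density `2|E|/(|V|(|V|−1))`; average local clustering coefficient with the
degree < 2 convention (coefficient 0); mean shortest-path length averaged
over connected ordered pairs only (the component count is logged when the
graph is disconnected). Degrees exclude self-interactions, which are
stored out-of-graph.

**Degree exponent.** `p(k) ∝ k^−γ` is fitted to the zero-truncated
empirical degree frequencies. The default is least squares on
log p(k) vs log k *weighted by √(bin count)*: in an unweighted fit the
many singleton bins in the tail all sit at the same log-frequency floor
and flatten the slope, biasing γ low by ≈ 0.2 at realistic sample sizes;
weighting by bin counts reflects the multinomial variance of the
log-frequencies and removes that bias (γ recovered within ±0.05 of truth
at 50k samples). An unweighted variant (`method="ls"`) and a discrete
truncated maximum-likelihood fit (`method="mle"`) are available. At least
3 distinct nonzero degrees are required.

## Synthetic data

The generator emulates the structure the pipeline assumes: dense,
location-coherent planted modules on a sparse background.

* Defaults: 300 proteins, 6 disjoint planted modules of 10–15 members,
  within-module edge probability 0.6, background edge probability 0.01,
  six locations, location coherence 0.9, 1–2 random labels per protein,
  seed 42. These sizes keep every test and example in the seconds range
  while leaving the modules clearly denser than the background
  (expected within-module degree ≈ 7 vs background ≈ 3).
* Each module has a home compartment; members carry it with probability
  0.9 on top of their random labels, so roughly one in ten within-module
  edges can lose co-localization — the location gate has real work to do.
* An optional preferential-attachment background replaces the Bernoulli
  background for degree-distribution tests.
* All randomness flows through one seeded numpy PCG64 generator: the same
  spec reproduces the same data bit for bit.
* What it does **not** emulate: overlapping complexes, hub proteins inside
  modules, correlated annotation noise, database-specific degree
  sequences, or realistic proteome scale. Passing the planted-recovery
  tests shows the pipeline works when its assumptions hold; it says
  nothing about curation artifacts in real interactomes.

A five-protein toy fixture encodes the canonical gating example: proteins
A and B interact and share partners P1, P2, P3; P1 and P3 co-localize with
both, P2 shares a compartment with A only. Hand evaluation gives
TOM(A,B) = 1.0 and LTOM(A,B) = 3/4, which the tests assert exactly.

## Known limitations

* The co-localization gate treats annotation as ground truth; incomplete
  annotation removes true interactions (lenient mode makes the loss
  explicit but cannot recover it).
* The greedy detector is a simplified ClusterONE variant; module
  boundaries can differ from the original program's on graphs where seed
  selection matters.
* The evaluation does not include composite scores (MMR, F-measure) or
  significance of Sn/PPV differences between networks.
* Identifier spaces are the user's responsibility; nothing maps between
  gene and protein accessions.
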