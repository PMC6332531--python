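# loctom

Co-localization-aware topological overlap for protein interaction networks:
filter a network to interactions whose partners share a subcellular
compartment, impute likely missing interactions from location-gated
topological overlap, detect protein modules, and benchmark them against
reference complexes and gene sets.

## Who this is for

Systems biologists working with protein–protein interaction (PPI) data who
want module (complex) prediction that respects the fact that only a subset
of catalogued interactions can physically occur — the partners must be in
the same cellular compartment. The package takes plain TSV edge lists,
a protein → location table, and optional reference complex catalogs and
gene sets; no database clients or identifier mapping are included.

## The model

For an undirected PPI network with adjacency `a_ij` and degrees `K_i`, the
**topological overlap** of proteins *i* and *j* is

```
TOM(i,j) = ( Σ_{u≠i,j} a_iu a_uj + a_ij ) / ( min(K_i, K_j) + 1 − a_ij )
```

— the fraction of the smaller neighborhood that is shared, folded together
with the direct edge, so `TOM ∈ [0,1]`. The **locational** variant gates
every numerator term by co-localization: a shared partner *u* counts only
if some compartment is common to *i*, *u* and *j* (`σ(i,u,j) = 1`), and the
direct edge counts only if *i* and *j* themselves co-localize (`σ′(i,j)`):

```
LTOM(i,j) = ( Σ_{u≠i,j} a_iu a_uj σ(i,u,j) + a_ij σ′(i,j) ) / ( min(K_i, K_j) + 1 − a_ij )
```

Gating only removes numerator terms, so `LTOM ≤ TOM` pointwise. Pairs
scoring above a threshold τ (default 0.5) that are not yet adjacent are
imputed as candidate interactions, producing an overlap-extended network
over the same proteins.

Modules are detected either by greedy growth of the cohesiveness

```
f(V) = w_in(V) / ( w_in(V) + w_bound(V) + p·|V| )
```

(ClusterONE-style, default penalty p = 2, size ≥ 10 and density ≥ 0.25
filters) or by Markov clustering (MCL, inflation 2.0). Predicted module
sets are scored against a reference catalog with clustering-wise
sensitivity `Sn`, positive predictive value `PPV`, and the geometric
accuracy `Acc = √(Sn·PPV)`; gene-set enrichment per module uses the
upper-tail hypergeometric test with Benjamini–Hochberg FDR, summarized by
the overrepresentation score `ORS` (fraction of modules significant at
adjusted p < 0.01).

## Worked example

The built-in generator plants six location-coherent modules (10–15 proteins,
within-module edge probability 0.6) on a 300-protein sparse background, then
the full pipeline runs on it:

```python
from loctom import (SyntheticSpec, generate, build_clpin, ltom_matrix,
                    impute_network, detect_modules_greedy, filter_modules,
                    sn_ppv_acc, ors_report)

data = generate(SyntheticSpec(seed=42))
clpin = build_clpin(data.network, data.localization)
scores = ltom_matrix(clpin, data.localization)
ltopin = impute_network(clpin, scores, tau=0.5)
mods = filter_modules(detect_modules_greedy(ltopin, p=2.0),
                      min_size=10, min_density=0.25)
sn, ppv, acc = sn_ppv_acc(mods, data.catalog)
rep = ors_report(mods, data.gene_set, background=set(ltopin.nodes))
```

which prints

```
GPIN : Network(300 nodes, 740 edges)
CLPIN: Network(237 nodes, 443 edges)
LTOPIN: Network(237 nodes, 657 edges)
modules: 7 sizes: [11, 11, 14, 16, 18, 18, 19]
Sn=0.9474 PPV=1.0000 Acc=0.9733
ORS=0.1429 significant=1/7
```

Reading the numbers: co-localization filtering removes interactions whose
endpoints share no compartment (740 → 443 edges, 300 → 237 proteins),
overlap imputation adds 214 high-scoring pairs back among the surviving
proteins, and greedy cohesiveness growth recovers the planted modules
almost perfectly (Sn 0.95, PPV 1.0). Exactly one module overlaps the
designated gene set strongly enough to be called enriched, so the
overrepresentation score is 1/7 ≈ 0.14.

The same pipeline is available from a shell:

```
loctom run --seed 42 --out-dir out/          # synthetic end-to-end run
loctom filter --edges gpin.tsv --localization loc.tsv --out clpin.tsv
loctom impute --edges clpin.tsv --localization loc.tsv --model ltom --out ltopin.tsv
loctom cluster --edges ltopin.tsv --algo greedy --out modules.tsv
loctom evaluate --modules modules.tsv --reference complexes.tsv
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, what the synthetic generator does and does not emulate,
and known limitations.
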