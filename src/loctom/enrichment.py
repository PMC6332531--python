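"""Gene-set overrepresentation in detected modules.

Each module of size n drawn from a background of N network proteins is
tested for enrichment of a gene set of size T via the upper-tail
hypergeometric probability of observing t or more set members in the
module. Raw p-values across the module set are adjusted with the
Benjamini-Hochberg step-up FDR procedure, and a module is called
significant when its adjusted p falls strictly below the cutoff
(default 0.01).

The module-set-level summary is the overrepresentation score,

    ORS = (# modules with adjusted p < cutoff) / (# modules),

reported together with the fraction of modules containing any gene-set
member and the fraction of gene-set members appearing in at least one
significant module (each member counted once even when modules overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .modules import ModuleSet


def hypergeom_test(t: int, n: int, T: int, N: int) -> float:
    """Upper-tail probability P(X >= t) for X ~ Hypergeometric(N, T, n).

    N is the background (network) size, T the gene-set size, n the module
    size and t the observed hits. Computed in log space by scipy, so it is
    stable for large N.
    """
    if not (0 <= t <= n <= N):
        raise ValueError(f"need 0 <= t <= n <= N, got t={t}, n={n}, N={N}")
    if not (0 <= T <= N):
        raise ValueError(f"need 0 <= T <= N, got T={T}, N={N}")
    if t == 0:
        return 1.0
    return float(hypergeom.sf(t - 1, N, T, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-module hypergeometric test outcome."""

    module_id: str
    t: int
    n: int
    T: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class ORSReport:
    """Module-set-level summary of gene-set overrepresentation."""

    U: int
    significant_count: int
    ors: float
    cancer_module_ratio: float
    cancer_gene_count: int
    cancer_gene_ratio: float
    cancer_gene_ratio_annotated: float
    results: tuple[EnrichmentResult, ...]

    def to_dict(self) -> dict:
        return {
            "module_number": self.U,
            "significant_count": self.significant_count,
            "ORS": self.ors,
            "cancer_module_ratio": self.cancer_module_ratio,
            "cancer_gene_count": self.cancer_gene_count,
            "cancer_gene_ratio": self.cancer_gene_ratio,
            "cancer_gene_ratio_annotated": self.cancer_gene_ratio_annotated,
        }


def ors_report(
    modules: ModuleSet,
    gene_set: set[str],
    background: set[str] | int,
    cutoff: float = 0.01,
) -> ORSReport:
    """Test every module against *gene_set* and summarize at the set level.

    *background* is the protein universe the modules were detected in —
    either the node set itself or its size. When the node set is given, the
    gene-set size T counts only members present in the background (the rest
    cannot be drawn into any module); the full gene-set size still serves as
    the alternative ratio denominator, since whether to divide by all genes
    or only by network-annotated ones is a reporting choice, and both are
    exposed.
    """
    if len(modules) == 0:
        raise ValueError("empty module set")
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    gene_set = set(gene_set)
    if isinstance(background, int):
        N = background
        annotated = gene_set
    else:
        N = len(background)
        annotated = gene_set & set(background)
    T = len(annotated)
    if T == 0:
        warnings.warn("gene set is disjoint from the background; all p-values are 1",
                      stacklevel=2)
    p_raw = []
    hits = []
    for m in modules.modules:
        t = len(m.members & gene_set)
        hits.append(t)
        p_raw.append(hypergeom_test(t, m.size, T, N) if T > 0 else 1.0)
    p_adj = bh_adjust(p_raw)
    results = tuple(
        EnrichmentResult(
            module_id=f"M{i + 1}",
            t=hits[i],
            n=modules.modules[i].size,
            T=T,
            N=N,
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
            significant=bool(p_adj[i] < cutoff),
        )
        for i in range(len(modules))
    )
    sig = [r for r in results if r.significant]
    genes_in_sig: set[str] = set()
    for r, m in zip(results, modules.modules):
        if r.significant:
            genes_in_sig |= m.members & gene_set
    u = len(modules)
    return ORSReport(
        U=u,
        significant_count=len(sig),
        ors=len(sig) / u,
        cancer_module_ratio=sum(1 for h in hits if h > 0) / u,
        cancer_gene_count=len(genes_in_sig),
        cancer_gene_ratio=len(genes_in_sig) / len(gene_set) if gene_set else 0.0,
        cancer_gene_ratio_annotated=len(genes_in_sig) / T if T else 0.0,
        results=results,
    )


def write_enrichment_tsv(report: ORSReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("#module_id\tn\tt\tp_raw\tp_adj\tsignificant\n")
        for r in report.results:
            fh.write(f"{r.module_id}\t{r.n}\t{r.t}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\t"
                     f"{int(r.significant)}\n")
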