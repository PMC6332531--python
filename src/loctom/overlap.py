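"""Topological overlap scores, with and without co-localization gating.

The topological overlap of proteins i and j combines their direct adjacency
a_ij with the number of interaction partners they share:

    TOM(i,j) = ( sum_{u != i,j} a_iu * a_uj  +  a_ij )
               / ( min(K_i, K_j) + 1 - a_ij )

The denominator bounds the score into [0,1]. The locational variant (LTOM)
keeps the denominator but gates each numerator term by co-localization: a
shared partner u counts only if some subcellular location is common to i, u
and j (the Boolean sigma(i,u,j)), and the direct edge counts only if i and j
themselves co-localize (sigma'(i,j)). Location-incoherent overlap therefore
only ever lowers the score, so LTOM <= TOM pointwise.

High-scoring non-adjacent pairs are candidate missing interactions;
:func:`impute_network` adds them as edges without recruiting new proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import LocalizationTable, MAJOR_LOCATIONS
from .network import Network


@dataclass
class OverlapMatrix:
    """Symmetric matrix of overlap scores in [0,1], diagonal 1 by convention."""

    scores: np.ndarray
    nodes: list[str]
    model_tag: str  # "TOM" | "LTOM"

    def __post_init__(self) -> None:
        s = self.scores
        if s.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("score matrix shape does not match node list")
        if not np.allclose(s, s.T):
            raise ValueError("score matrix is not symmetric")
        if s.min() < 0 or s.max() > 1 + 1e-12:
            raise ValueError("overlap scores must lie in [0,1]")

    def score(self, u: str, v: str) -> float:
        i, j = self.nodes.index(u), self.nodes.index(v)
        return float(self.scores[i, j])

    def write_tsv(self, path: str | Path) -> None:
        """Long-form export: node1, node2, score for every unordered pair i<j."""
        with open(path, "w") as fh:
            fh.write("#node1\tnode2\tscore\n")
            n = len(self.nodes)
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(f"{self.nodes[i]}\t{self.nodes[j]}\t{self.scores[i, j]:.10g}\n")


def _location_masks(nodes: list[str], loc: LocalizationTable, strict: bool) -> np.ndarray:
    """Per-node bitmasks over the six major locations; 0 for unannotated."""
    bit = {name: 1 << b for b, name in enumerate(MAJOR_LOCATIONS)}
    masks = np.zeros(len(nodes), dtype=np.int64)
    missing = []
    for idx, n in enumerate(nodes):
        labels = loc.get(n)
        if not labels:
            missing.append(n)
            continue
        for lab in labels:
            masks[idx] |= bit[lab]
    if missing and strict:
        raise ValueError(f"{len(missing)} network nodes lack localization, e.g. {missing[:5]}")
    return masks


def _denominator(adj: np.ndarray) -> np.ndarray:
    deg = adj.sum(axis=1)
    den = np.minimum.outer(deg, deg) + 1 - adj
    assert den.min() >= 1, "overlap denominator must be >= 1"
    return den


def tom_matrix(net: Network) -> OverlapMatrix:
    """Topological overlap scores for every node pair of *net*.

    The shared-partner sum runs over u outside {i,j}; because the adjacency
    diagonal is zero, the plain matrix square already realizes that
    convention. Pairs involving an isolated node score 0 off-diagonal.
    """
    adj = net.adjacency_matrix()
    numer = adj @ adj + adj
    scores = numer / _denominator(adj)
    np.fill_diagonal(scores, 1.0)
    return OverlapMatrix(scores=scores, nodes=net.nodes, model_tag="TOM")


def ltom_matrix(net: Network, loc: LocalizationTable, strict: bool = False) -> OverlapMatrix:
    """Location-gated topological overlap scores.

    In lenient mode (default) unannotated nodes get an empty location set, so
    every gate involving them is closed — co-localization is never fabricated.
    Strict mode raises instead.
    """
    adj = net.adjacency_matrix()
    masks = _location_masks(net.nodes, loc, strict)
    pair_mask = masks[:, None] & masks[None, :]  # common locations of (i,j)

    numer = np.zeros_like(adj, dtype=np.float64)
    # Group pairs by their common-location bitmask m: the gated shared-partner
    # count is (A diag(c_m) A)_ij with c_m[u] = 1 iff u touches m.  At most
    # 2^6 distinct masks exist, so this stays a handful of matrix products.
    for m in np.unique(pair_mask):
        if m == 0:
            continue
        sel = pair_mask == m
        gate = ((masks & m) != 0).astype(np.int64)
        numer[sel] = ((adj * gate[None, :]) @ adj)[sel]
    numer += adj * (pair_mask != 0)
    scores = numer / _denominator(adj)
    np.fill_diagonal(scores, 1.0)
    return OverlapMatrix(scores=scores, nodes=net.nodes, model_tag="LTOM")


def sigma(i: str, u: str, j: str, loc: LocalizationTable) -> int:
    """1 iff some subcellular location is common to all of i, u and j."""
    return int(bool(loc.get(i) & loc.get(u) & loc.get(j)))


def sigma_prime(i: str, j: str, loc: LocalizationTable) -> int:
    """1 iff i and j share at least one subcellular location."""
    return int(bool(loc.get(i) & loc.get(j)))


def impute_network(
    base: Network,
    scores: OverlapMatrix,
    tau: float = 0.5,
    keep_base_edges: bool = True,
) -> Network:
    """Add high-overlap non-edges to *base* as imputed interactions.

    The node set never changes: only potential interactions among existing
    proteins are added, each tagged ``imputed=True``. *tau* must be positive
    — a non-positive threshold would add every pair sharing any neighbor.
    """
    if tau <= 0:
        raise ValueError("imputation threshold tau must be > 0")
    if scores.nodes != base.nodes:
        raise ValueError("score matrix is not indexed by the base network's nodes")
    out = Network()
    for n in base.nodes:
        out.add_node(n)
    out.self_pairs = set(base.self_pairs)
    if keep_base_edges:
        for u, v in base.edges():
            out.add_edge(u, v, **base.edge_data(u, v))
    nodes = base.nodes
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if not base.has_edge(nodes[i], nodes[j]) and scores.scores[i, j] >= tau:
                out.add_edge(nodes[i], nodes[j], imputed=True)
    return out


def impute_top_k(base: Network, scores: OverlapMatrix, k: int, keep_base_edges: bool = True) -> Network:
    """Add the k highest-scoring non-edges (ties broken by node-pair order)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    nodes = base.nodes
    n = len(nodes)
    candidates = [
        (scores.scores[i, j], i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if not base.has_edge(nodes[i], nodes[j])
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    out = Network()
    for node in nodes:
        out.add_node(node)
    out.self_pairs = set(base.self_pairs)
    if keep_base_edges:
        for u, v in base.edges():
            out.add_edge(u, v, **base.edge_data(u, v))
    for _, i, j in candidates[:k]:
        out.add_edge(nodes[i], nodes[j], imputed=True)
    return out
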