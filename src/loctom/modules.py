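"""Module detection: cohesiveness-guided greedy growth and Markov clustering.

The greedy detector is a documented, simplified variant of the
ClusterONE-style procedure: grow a candidate set from a seed vertex, at each
step applying the single vertex addition or removal that most increases the
cohesiveness

    f(V) = w_in(V) / ( w_in(V) + w_bound(V) + p * |V| )

where w_in counts (possibly weighted) edges with both ends inside V, w_bound
counts edges with exactly one end inside, and p*|V| penalizes small sets to
model network incompleteness. Growth stops at a local maximum; overlapping
results are merged by the overlap score omega(A,B) = |A n B|^2 / (|A||B|).
Exact agreement with the original ClusterONE program is a non-goal.

Markov clustering (MCL) alternates expansion (matrix squaring) with
inflation (entrywise power + column renormalization) on the column-stochastic
walk matrix until it stabilizes, then reads hard clusters off the support of
the limit matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import Network


@dataclass(frozen=True)
class Module:
    """A candidate functional module: a set of >= 2 proteins with its scores."""

    members: frozenset[str]
    cohesiveness: float
    w_in: float
    w_bound: float
    density: float

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a module needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    """Possibly overlapping modules plus provenance of how they were found."""

    modules: list[Module]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for m in self.modules:
            if m.members in seen:
                raise ValueError("duplicate module member sets")
            seen.add(m.members)

    def __len__(self) -> int:
        return len(self.modules)

    def member_sets(self) -> list[frozenset[str]]:
        return [m.members for m in self.modules]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#module_id\tsize\tdensity\tcohesiveness\tmembers\n")
            for idx, m in enumerate(self.modules, start=1):
                fh.write(
                    f"M{idx}\t{m.size}\t{m.density:.6g}\t{m.cohesiveness:.6g}\t"
                    + ",".join(sorted(m.members))
                    + "\n"
                )


def _edge_weight(net: Network, u: str, v: str, weighted: bool) -> float:
    if not weighted:
        return 1.0
    return float(net.edge_data(u, v).get("weight", 1.0))


def _in_bound(members: frozenset[str], net: Network, weighted: bool) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v in net.neighbors(u):
            w = _edge_weight(net, u, v, weighted)
            if v in members:
                w_in += w / 2.0  # each internal edge visited from both ends
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(members, net: Network, p: float = 2.0, weighted: bool = False) -> float:
    """f(V) = w_in / (w_in + w_bound + p|V|) for the vertex set *members*."""
    members = frozenset(members)
    if not members:
        raise ValueError("empty member set")
    if p < 0:
        raise ValueError("penalty p must be >= 0")
    missing = [m for m in members if m not in set(net.nodes)]
    if missing:
        raise ValueError(f"members not in network: {missing[:5]}")
    w_in, w_bound = _in_bound(members, net, weighted)
    denom = w_in + w_bound + p * len(members)
    return w_in / denom if denom > 0 else 0.0


def _module_density(members: frozenset[str], net: Network) -> float:
    k = len(members)
    if k < 2:
        return 0.0
    internal = sum(1 for u in members for v in net.neighbors(u) if v in members) // 2
    return internal / (k * (k - 1) / 2)


def _make_module(members: frozenset[str], net: Network, p: float, weighted: bool) -> Module:
    w_in, w_bound = _in_bound(members, net, weighted)
    denom = w_in + w_bound + p * len(members)
    return Module(
        members=members,
        cohesiveness=w_in / denom if denom > 0 else 0.0,
        w_in=w_in,
        w_bound=w_bound,
        density=_module_density(members, net),
    )


def _grow_from_seed(seed: str, net: Network, p: float, weighted: bool) -> frozenset[str]:
    members = {seed}
    f = cohesiveness(members, net, p, weighted)
    while True:
        best_gain = 0.0
        best_move: tuple[str, str] | None = None
        boundary = sorted({v for u in members for v in net.neighbors(u)} - members)
        for v in boundary:
            cand = cohesiveness(members | {v}, net, p, weighted)
            if cand - f > best_gain + 1e-12:
                best_gain, best_move = cand - f, ("add", v)
        if len(members) > 2:
            for v in sorted(members):
                cand = cohesiveness(members - {v}, net, p, weighted)
                if cand - f > best_gain + 1e-12:
                    best_gain, best_move = cand - f, ("remove", v)
        if best_move is None:
            return frozenset(members)
        op, v = best_move
        members = members | {v} if op == "add" else members - {v}
        f += best_gain


def overlap_score(a: frozenset[str], b: frozenset[str]) -> float:
    """omega(A,B) = |A n B|^2 / (|A| |B|), the match score used for merging."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def detect_modules_greedy(
    net: Network,
    p: float = 2.0,
    overlap_merge_threshold: float = 0.8,
    weighted: bool = False,
) -> ModuleSet:
    """Greedy cohesiveness growth from every uncovered seed, then merge.

    Seeds are processed in descending degree (ties by ID), skipping nodes
    already inside a grown module, so the output is deterministic for a
    given network.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    order = sorted(net.nodes, key=lambda n: (-net.degree(n), n))
    covered: set[str] = set()
    raw: list[frozenset[str]] = []
    for seed in order:
        if seed in covered or net.degree(seed) == 0:
            continue
        grown = _grow_from_seed(seed, net, p, weighted)
        if len(grown) >= 2 and grown not in raw:
            raw.append(grown)
        covered |= grown
    # merge highly overlapping clusters until a fixed point
    merged = True
    while merged:
        merged = False
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                if overlap_score(raw[i], raw[j]) >= overlap_merge_threshold:
                    union = raw[i] | raw[j]
                    raw = [raw[k] for k in range(len(raw)) if k not in (i, j)]
                    if union not in raw:
                        raw.append(union)
                    merged = True
                    break
            if merged:
                break
    modules = [_make_module(m, net, p, weighted) for m in raw]
    return ModuleSet(
        modules=modules,
        provenance={"algorithm": "greedy-cohesiveness", "p": p,
                    "overlap_merge_threshold": overlap_merge_threshold, "weighted": weighted},
    )


def detect_modules_mcl(
    net: Network,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
    weighted: bool = False,
) -> ModuleSet:
    """Markov clustering: hard, non-overlapping clusters of *net*.

    Entries below *prune* are zeroed after each inflation for tractability;
    this can change clusters on pathological inputs. Clusters smaller than 2
    (singleton attractors) are discarded.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = net.nodes
    adj = net.adjacency_matrix().astype(np.float64)
    if weighted:
        for u, v in net.edges():
            i, j = nodes.index(u), nodes.index(v)
            adj[i, j] = adj[j, i] = _edge_weight(net, u, v, True)
    m = adj + np.eye(len(nodes))  # self-loops stabilize the walk
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m                     # expansion
        m = np.power(m, inflation)    # inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        assert np.all(np.abs(m.sum(axis=0) - 1.0) < 1e-9)
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; returning current attractor structure",
                      stacklevel=2)
    # clusters = connected components of the limit matrix's support
    support = (m + m.T) > tol
    np.fill_diagonal(support, True)
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(support, directed=False)
    clusters: dict[int, set[str]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, set()).add(nodes[idx])
    modules = [
        _make_module(frozenset(c), net, p=0.0, weighted=weighted)
        for c in clusters.values()
        if len(c) >= 2
    ]
    modules.sort(key=lambda mod: sorted(mod.members))
    return ModuleSet(
        modules=modules,
        provenance={"algorithm": "mcl", "inflation": inflation, "max_iter": max_iter,
                    "tol": tol, "prune": prune, "p": 0.0, "weighted": weighted},
    )


def filter_modules(mods: ModuleSet, min_size: int = 10, min_density: float = 0.25) -> ModuleSet:
    """Retain modules with size >= min_size and internal density >= min_density."""
    kept = [m for m in mods.modules if m.size >= min_size and m.density >= min_density]
    prov = dict(mods.provenance)
    prov.update({"min_size": min_size, "min_density": min_density})
    return ModuleSet(modules=kept, provenance=prov)
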