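"""Core network container, the co-localization filter, and global statistics.

The :class:`Network` wraps an undirected simple graph with a stable node
order (needed so score matrices are well indexed), keeps self-interactions
out of the graph proper, and carries optional per-edge metadata.

The statistics here are the ones a network paper reports for each
constructed interaction network: density, average local clustering
coefficient, average shortest-path length, and the degree exponent gamma of
a power-law fit p(k) ~ k^-gamma to the degree distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Iterator

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar

if TYPE_CHECKING:  # pragma: no cover
    from .io import LocalizationTable

logger = logging.getLogger(__name__)


class Network:
    """Undirected simple graph over protein IDs with a stable node order.

    Self-interactions are recorded in :attr:`self_pairs` but never stored as
    graph edges: they contribute neither to degree nor to shared-neighbor
    counts.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()
        self._order: list[str] = []
        self.self_pairs: set[str] = set()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> "Network":
        net = cls()
        for n in nodes:
            net.add_node(n)
        for u, v in edges:
            net.add_edge(u, v)
        return net

    def add_node(self, n: str) -> None:
        if n not in self._g:
            self._g.add_node(n)
            self._order.append(n)

    def add_edge(self, u: str, v: str, **metadata) -> None:
        if u == v:
            raise ValueError(f"self-pair {u!r}: record via Network.self_pairs, not as an edge")
        self.add_node(u)
        self.add_node(v)
        if not self._g.has_edge(u, v):
            self._g.add_edge(u, v, **metadata)

    # -- views ------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._order)

    def edges(self) -> Iterator[tuple[str, str]]:
        return iter(self._g.edges())

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def edge_data(self, u: str, v: str) -> dict:
        return dict(self._g.edges[u, v])

    def neighbors(self, n: str) -> set[str]:
        return set(self._g.neighbors(n))

    def degree(self, n: str) -> int:
        return self._g.degree(n)

    def degree_vector(self) -> np.ndarray:
        """Integer degrees K_i in node order (self-pairs excluded)."""
        return np.array([self._g.degree(n) for n in self._order], dtype=np.int64)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency with zero diagonal, in node order."""
        return nx.to_numpy_array(self._g, nodelist=self._order, dtype=np.int64)

    def subgraph_edges(self, keep: Iterable[tuple[str, str]], nodes: Iterable[str]) -> "Network":
        """New network over *nodes* with exactly the edges in *keep*."""
        out = Network()
        for n in nodes:
            out.add_node(n)
        for u, v in keep:
            out.add_edge(u, v, **self.edge_data(u, v))
        out.self_pairs = {n for n in self.self_pairs if n in out._g}
        return out

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            set(self._order) == set(other._order)
            and set(map(frozenset, self._g.edges())) == set(map(frozenset, other._g.edges()))
        )

    def __repr__(self) -> str:
        return f"Network({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class PowerLawFit:
    """Degree exponent gamma of p(k) ~ k^-gamma with fit diagnostics."""

    gamma: float
    fit_range: tuple[int, int]
    r_squared: float
    method: str

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("degree exponent must be positive")


def build_clpin(
    gpin: Network, loc: "LocalizationTable", drop_unannotated: bool = True
) -> Network:
    """Restrict a network to co-localized interactions.

    An edge survives iff its endpoints share at least one major subcellular
    location; edges with an unannotated endpoint are removed. Nodes left
    isolated by the filtering are dropped when *drop_unannotated* is true
    (the default), so the co-localization network shrinks in proteins as
    well as in interactions.
    """
    if len(loc) == 0:
        raise ValueError("localization table is empty")
    kept = [(u, v) for u, v in gpin.edges() if loc.get(u) & loc.get(v)]
    if drop_unannotated:
        covered = {n for e in kept for n in e}
        nodes = [n for n in gpin.nodes if n in covered]
    else:
        nodes = gpin.nodes
    clpin = gpin.subgraph_edges(kept, nodes)
    logger.info(
        "co-localization filter: %d/%d edges kept, %d/%d nodes kept",
        clpin.n_edges, gpin.n_edges, clpin.n_nodes, gpin.n_nodes,
    )
    return clpin


def density(net: Network) -> float:
    """Fraction of realized node pairs: 2|E| / (|V|(|V|-1))."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return 2.0 * net.n_edges / (n * (n - 1))


def avg_clustering_coefficient(net: Network) -> float:
    """Local clustering coefficient averaged over all nodes (degree<2 -> 0)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return nx.average_clustering(net.to_networkx())


def avg_path_length(net: Network) -> float:
    """Mean shortest-path length over connected ordered pairs.

    Disconnected graphs are handled by averaging within components only;
    the component count is logged so the caveat is visible.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = net.to_networkx()
    n_comp = nx.number_connected_components(g)
    if n_comp > 1:
        logger.info("network has %d components; path length averaged within components", n_comp)
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        m = len(comp)
        if m < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())  # includes d(u,u)=0
        pairs += m * (m - 1)
    if pairs == 0:
        raise ValueError("no connected pairs: path length undefined")
    return total / pairs


def fit_power_law(degrees: np.ndarray, method: str = "wls") -> PowerLawFit:
    """Fit p(k) ~ k^-gamma to an empirical degree distribution.

    Degree-0 nodes are excluded and only degrees with nonzero frequency
    enter the fit. Methods:

    ``wls`` (default)
        Least squares on log p(k) vs log k, weighted by sqrt(bin count).
        The weighting reflects the multinomial variance of log-frequencies;
        unweighted log-log regression lets singleton tail bins flatten the
        slope and systematically underestimates gamma.
    ``ls``
        Classic unweighted log-log least squares.
    ``mle``
        Maximum likelihood for the discrete power law truncated to the
        observed degree range.
    """
    degrees = np.asarray(degrees)
    ks = degrees[degrees > 0]
    vals, counts = np.unique(ks, return_counts=True)
    if len(vals) < 3:
        raise ValueError(f"power-law fit needs >= 3 distinct nonzero degrees, got {len(vals)}")
    kmin, kmax = int(vals.min()), int(vals.max())
    freq = counts / counts.sum()
    logk, logp = np.log(vals.astype(float)), np.log(freq)
    if method in ("wls", "ls"):
        w = np.sqrt(counts) if method == "wls" else None
        (slope, intercept), res = np.polyfit(logk, logp, 1, w=w, full=False), None
        pred = slope * logk + intercept
        weights = counts if method == "wls" else np.ones_like(counts)
        ybar = np.average(logp, weights=weights)
        ss_res = np.sum(weights * (logp - pred) ** 2)
        ss_tot = np.sum(weights * (logp - ybar) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        gamma = -slope
    elif method == "mle":
        support = np.arange(kmin, kmax + 1, dtype=float)
        n = counts.sum()
        sum_logk = float((counts * logk).sum())

        def nll(g: float) -> float:
            return g * sum_logk + n * np.log(np.sum(support ** -g))

        opt = minimize_scalar(nll, bounds=(0.05, 10.0), method="bounded")
        gamma, r2 = float(opt.x), float("nan")
    else:
        raise ValueError(f"unknown fit method {method!r}")
    if gamma <= 0:
        raise ValueError(f"fitted exponent {gamma:.3f} is not positive: degrees not power-law-like")
    return PowerLawFit(gamma=float(gamma), fit_range=(kmin, kmax), r_squared=float(r2), method=method)


def network_stats(net: Network, fit_method: str = "wls") -> dict:
    """The summary table computed for each constructed network."""
    stats = {
        "proteins": net.n_nodes,
        "interactions": net.n_edges,
        "density": density(net),
        "avg_clustering_coefficient": avg_clustering_coefficient(net),
        "avg_path_length": avg_path_length(net),
    }
    try:
        stats["degree_exponent"] = fit_power_law(net.degree_vector(), method=fit_method).gamma
    except ValueError as exc:
        logger.info("degree-exponent fit skipped: %s", exc)
        stats["degree_exponent"] = None
    return stats
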