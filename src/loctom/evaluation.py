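"""Benchmarking predicted modules and edge predictions.

Module sets are compared with a reference complex catalog through the
overlap table t_ij = |predicted_i n reference_j|:

    Sn  = sum_j max_i t_ij / sum_j |reference_j|      (clustering-wise sensitivity)
    PPV = sum_i max_j t_ij / sum_i sum_j t_ij         (positive predictive value)
    Acc = sqrt(Sn * PPV)                              (geometric accuracy)

The Sn denominator weights each reference complex by its size, the standard
clustering-wise sensitivity, which keeps Sn in [0,1]. Reference complexes are
not shrunk to the predicted network's protein universe.

Edge-level predictions are scored against labeled positive/negative
interaction sets with precision, recall and Matthews correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .io import ComplexCatalog, LocalizationTable
from .modules import ModuleSet
from .network import Network

SetsLike = Union[ModuleSet, ComplexCatalog, Sequence[Iterable[str]]]


def _as_sets(obj: SetsLike) -> list[frozenset[str]]:
    if isinstance(obj, ModuleSet):
        return obj.member_sets()
    if isinstance(obj, ComplexCatalog):
        return obj.member_sets()
    return [frozenset(s) for s in obj]


def overlap_table(predicted: SetsLike, reference: SetsLike) -> np.ndarray:
    """r x s integer matrix of pairwise intersection sizes."""
    pred, ref = _as_sets(predicted), _as_sets(reference)
    t = np.zeros((len(pred), len(ref)), dtype=np.int64)
    for i, p in enumerate(pred):
        for j, c in enumerate(ref):
            t[i, j] = len(p & c)
    return t


def geometric_accuracy(sn: float, ppv: float) -> float:
    """Acc = sqrt(Sn * PPV), the geometric mean of the two benchmark scores."""
    if not (0 <= sn <= 1 and 0 <= ppv <= 1):
        raise ValueError("Sn and PPV must lie in [0,1]")
    return math.sqrt(sn * ppv)


def sn_ppv_acc(predicted: SetsLike, reference: SetsLike) -> tuple[float, float, float]:
    """Clustering-wise sensitivity, PPV and their geometric accuracy."""
    pred, ref = _as_sets(predicted), _as_sets(reference)
    if not pred or not ref:
        raise ValueError("predicted and reference sets must both be nonempty")
    t = overlap_table(pred, ref)
    w = np.array([len(c) for c in ref], dtype=np.int64)
    sn = float(t.max(axis=0).sum() / w.sum())
    total = t.sum()
    ppv = float(t.max(axis=1).sum() / total) if total > 0 else 0.0
    return sn, ppv, geometric_accuracy(sn, ppv)


@dataclass(frozen=True)
class EdgePredictionScores:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    mcc: float


def _norm_edges(edges: Iterable) -> set[frozenset[str]]:
    return {frozenset(e) for e in edges}


def edge_prediction_scores(
    predicted_edges: Iterable, positive_set: Iterable, negative_set: Iterable
) -> EdgePredictionScores:
    """Confusion-matrix scores of an edge prediction against labeled sets.

    Only edges in the positive or negative universe are scored; the two
    labeled sets must be disjoint. MCC is defined as 0 when any marginal of
    the confusion matrix is 0.
    """
    pred = _norm_edges(predicted_edges)
    pos = _norm_edges(positive_set)
    neg = _norm_edges(negative_set)
    if pos & neg:
        raise ValueError("positive and negative edge sets overlap")
    tp = len(pred & pos)
    fn = len(pos - pred)
    fp = len(pred & neg)
    tn = len(neg - pred)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return EdgePredictionScores(tp, fp, tn, fn, precision, recall, mcc)


def coloc_ratio(net: Network, loc: LocalizationTable) -> float:
    """Fraction of edges whose endpoints share >= 1 subcellular location."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    shared = sum(1 for u, v in net.edges() if loc.get(u) & loc.get(v))
    return shared / net.n_edges


def flag_ratio(net: Network, flag_column: str) -> float:
    """Fraction of edges whose metadata flag *flag_column* is truthy."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    n_set = 0
    for u, v in net.edges():
        data = net.edge_data(u, v)
        if flag_column not in data:
            raise KeyError(f"edge ({u},{v}) lacks metadata column {flag_column!r}")
        if data[flag_column] in (1, "1", True):
            n_set += 1
    return n_set / net.n_edges
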