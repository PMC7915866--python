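"""Mutual-information functional networks.

Each recording channel is a node.  Pairwise statistical dependence is
measured by histogram mutual information

    MI(S, Q) = H(S) + H(Q) - H(S, Q),

with marginal and joint entropies estimated from equal-width histograms
(default B = 16 bins per channel over the observed range).  The normalized
MI matrix is the weighted adjacency A(a_ij); thresholding it at TH gives the
sparse binary undirected functional network, with TH chosen as the largest
grid value whose network (1) stays connected with no isolated nodes and
(2) keeps average degree above 2 ln n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .preprocess import Segment

__all__ = [
    "HistogramModel",
    "WeightedNet",
    "BinaryNet",
    "ThresholdSelectionError",
    "channel_entropy",
    "joint_entropy",
    "mutual_information",
    "normalized_mutual_information",
    "build_mi_matrix",
    "binarize",
    "select_threshold",
]


# ---------------------------------------------------------------------------
# histogram model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistogramModel:
    """Joint equal-width histogram of two channels.

    Marginals are the row/column sums of the joint table, so the model is
    internally consistent by construction.
    """

    bins: int
    edges_s: np.ndarray
    edges_q: np.ndarray
    joint: np.ndarray  # (B, B) probabilities

    @property
    def marginal_s(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def marginal_q(self) -> np.ndarray:
        return self.joint.sum(axis=0)


def _check_series(x: np.ndarray, bins: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    if x.size < bins:
        raise ValueError(f"series length {x.size} < bin count {bins}")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    return x


def _edges(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if lo == hi:  # constant series: a single occupied bin, entropy 0
        hi = lo + 1.0
    return np.linspace(lo, hi, bins + 1)


def joint_histogram(s, q, bins: int = 16) -> HistogramModel:
    """Equal-width joint histogram over the observed range of each channel."""
    s = _check_series(s, bins)
    q = _check_series(q, bins)
    if s.size != q.size:
        raise ValueError(f"length mismatch: {s.size} vs {q.size}")
    es, eq = _edges(s, bins), _edges(q, bins)
    counts, _, _ = np.histogram2d(s, q, bins=[es, eq])
    return HistogramModel(bins=bins, edges_s=es, edges_q=eq, joint=counts / s.size)


def _entropy_from_probs(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def channel_entropy(series, bins: int = 16) -> float:
    """Shannon entropy (bits) of one channel's histogram distribution."""
    x = _check_series(series, bins)
    counts, _ = np.histogram(x, bins=_edges(x, bins))
    return _entropy_from_probs(counts / x.size)


def joint_entropy(s, q, bins: int = 16) -> float:
    """Joint Shannon entropy (bits) of two channels on a B x B grid."""
    return _entropy_from_probs(joint_histogram(s, q, bins).joint.ravel())


def mutual_information(s, q, bins: int = 16) -> float:
    """Histogram mutual information MI = H(S) + H(Q) - H(S,Q), in bits.

    Clipped at zero: the identity is exact for the histogram model, so any
    negative value is floating-point noise.
    """
    model = joint_histogram(s, q, bins)
    mi = (
        _entropy_from_probs(model.marginal_s)
        + _entropy_from_probs(model.marginal_q)
        - _entropy_from_probs(model.joint.ravel())
    )
    return max(mi, 0.0)


def normalized_mutual_information(s, q, bins: int = 16, method: str = "geometric") -> float:
    """MI scaled into [0, 1].

    ``geometric`` divides by sqrt(H(S) H(Q)); since MI <= min(H(S), H(Q)) the
    result is intrinsically bounded by 1.  Degenerate channels (zero
    entropy) share no information and score 0.
    """
    if method != "geometric":
        raise ValueError(f"unknown normalization {method!r}")
    model = joint_histogram(s, q, bins)
    hs = _entropy_from_probs(model.marginal_s)
    hq = _entropy_from_probs(model.marginal_q)
    if hs == 0.0 or hq == 0.0:
        return 0.0
    mi = max(hs + hq - _entropy_from_probs(model.joint.ravel()), 0.0)
    return min(mi / math.sqrt(hs * hq), 1.0)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


@dataclass
class WeightedNet:
    """Normalized MI adjacency: symmetric, zero diagonal, entries in [0, 1]."""

    labels: Sequence[str]
    weights: np.ndarray
    normalization: str = "geometric"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} labels")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.labels), columns=list(self.labels))


@dataclass
class BinaryNet:
    """Thresholded functional network: 0/1 symmetric adjacency."""

    labels: Sequence[str]
    adjacency: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.labels)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} does not match {n} labels")
        a = (a != 0).astype(np.int8)
        if not (a == a.T).all():
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, 0)
        self.adjacency = a

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> list[tuple[str, str]]:
        labs = list(self.labels)
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(labs[i], labs[j]) for i, j in zip(ii, jj)]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edge_list())
        return g


def build_mi_matrix(
    segments: Sequence[Segment],
    bins: int = 16,
    normalization: str = "geometric",
) -> WeightedNet:
    """Average per-segment normalized MI matrices into one weighted network.

    Every segment (one per movement repetition) yields its own pairwise
    normalized-MI matrix; the repetition matrices are averaged arithmetically.
    """
    if not segments:
        raise ValueError("need at least one segment")
    labels = list(segments[0].labels)
    for seg in segments[1:]:
        if list(seg.labels) != labels:
            raise ValueError("segments have mismatched channel sets")
    n = len(labels)
    acc = np.zeros((n, n))
    for seg in segments:
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                w[i, j] = w[j, i] = normalized_mutual_information(
                    seg.data[:, i], seg.data[:, j], bins=bins, method=normalization
                )
        acc += w
    acc /= len(segments)
    return WeightedNet(labels=labels, weights=acc, normalization=normalization)


def binarize(net: WeightedNet, threshold: float) -> BinaryNet:
    """Edge iff normalized MI strictly exceeds the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    adj = (net.weights > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryNet(labels=list(net.labels), adjacency=adj, threshold=threshold)


class ThresholdSelectionError(RuntimeError):
    """No threshold met both selection principles; carries the scan trace."""

    def __init__(self, message: str, trace: pd.DataFrame):
        super().__init__(message)
        self.trace = trace


def select_threshold(net: WeightedNet, step: float = 0.01) -> tuple[float, pd.DataFrame]:
    """Scan TH over a grid and pick the largest feasible value.

    Feasibility at a threshold requires (1) a single connected component
    with no isolated nodes and (2) average degree above ``2 ln n``.  The
    returned trace records average degree, isolated-node count, component
    count and feasibility for every grid value, mirroring the diagnostic
    curves used to justify a threshold choice.
    """
    n = net.n
    bound = 2.0 * math.log(n)
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    rows = []
    best = None
    for th in grid:
        adj = (net.weights > th).astype(np.int8)
        np.fill_diagonal(adj, 0)
        deg = adj.sum(axis=1)
        n_comp, _ = connected_components(adj, directed=False)
        n_iso = int((deg == 0).sum())
        avg = float(deg.mean())
        feasible = (n_comp == 1) and (n_iso == 0) and (avg > bound)
        rows.append(
            {
                "threshold": float(th),
                "avg_degree": avg,
                "n_isolated": n_iso,
                "n_components": int(n_comp),
                "feasible": feasible,
            }
        )
        if feasible:
            best = float(th)
    trace = pd.DataFrame(rows)
    if best is None:
        raise ThresholdSelectionError(
            f"no threshold keeps the network connected with <k> > 2 ln n = {bound:.2f}",
            trace,
        )
    return best, trace
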