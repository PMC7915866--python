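"""Node importance by the contraction method.

Cohesion of a connected network M with n nodes and average path length L is

    cohesion(M) = 1 / (n L) = (n - 1) / sum_{i != j} d_ij .

Contracting node i merges i and its whole neighbourhood into one supernode
(parallel edges collapse, self-loops are dropped), leaving n - k_i nodes.
The importance of node i is the relative cohesion gain of that contraction:

    IMC(i) = 1 - cohesion(M) / cohesion(M x i).

A node whose contraction collapses the network to a single point gets the
maximal score: the cohesion of a one-node network is defined as 1, which is
also the supremum 1/(nL) can approach.  Scores are computed per movement
condition; key nodes are those whose importance exceeds a threshold
(default 0.5), unioned across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .minet import BinaryNet
from .netmetrics import DisconnectedError, _component_sizes, avg_path_length, is_connected

__all__ = [
    "ImportanceVector",
    "cohesion",
    "contract_node",
    "node_importance",
    "select_key_nodes",
]


@dataclass(frozen=True)
class ImportanceVector:
    """Per-node contraction-importance scores of one connected network."""

    labels: tuple[str, ...]
    imc: tuple[float, ...]
    cohesion: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.imc))

    def above(self, threshold: float) -> list[str]:
        return [lab for lab, v in zip(self.labels, self.imc) if v > threshold]


def _require_connected(net: BinaryNet) -> None:
    if net.n > 1 and not is_connected(net):
        raise DisconnectedError(_component_sizes(net))


def cohesion(net: BinaryNet) -> float:
    """Cohesion 1/(n L); a single-node network has cohesion 1 by convention."""
    if net.n == 1:
        return 1.0
    _require_connected(net)
    return 1.0 / (net.n * avg_path_length(net))


def contract_node(net: BinaryNet, label: str) -> BinaryNet:
    """Merge ``label`` and all its neighbours into one supernode.

    Edges incident to the merged set reattach to the supernode; duplicate
    edges collapse and self-loops are dropped.  The result has
    ``n - k_i`` nodes and is connected whenever the input is.
    """
    labs = list(net.labels)
    i = labs.index(label)
    a = net.adjacency
    merged = np.zeros(net.n, dtype=bool)
    merged[i] = True
    merged[a[i] != 0] = True
    keep = np.nonzero(~merged)[0]

    m = len(keep) + 1
    new_labels = [f"{label}*"] + [labs[j] for j in keep]
    adj = np.zeros((m, m), dtype=np.int8)
    sub = a[np.ix_(keep, keep)]
    adj[1:, 1:] = sub
    # any edge from a kept node into the merged set becomes an edge to the supernode
    to_super = (a[np.ix_(keep, np.nonzero(merged)[0])].sum(axis=1) > 0).astype(np.int8)
    adj[0, 1:] = to_super
    adj[1:, 0] = to_super
    return BinaryNet(labels=new_labels, adjacency=adj, threshold=net.threshold)


def node_importance(net: BinaryNet) -> ImportanceVector:
    """Contraction importance IMC(i) for every node of a connected network."""
    if net.n < 2:
        raise ValueError("importance needs at least two nodes")
    _require_connected(net)
    base = cohesion(net)
    scores = []
    for lab in net.labels:
        contracted = contract_node(net, lab)
        scores.append(1.0 - base / cohesion(contracted))
    return ImportanceVector(labels=tuple(net.labels), imc=tuple(scores), cohesion=base)


def select_key_nodes(
    importances: ImportanceVector | Mapping[str, ImportanceVector],
    threshold: float = 0.5,
) -> list[str]:
    """Labels with IMC above the threshold; unioned across conditions.

    Accepts either a single :class:`ImportanceVector` or a mapping from
    condition label to vector.  Returns labels in the channel order of the
    first vector; an empty selection triggers a warning, not an error.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1)")
    if isinstance(importances, ImportanceVector):
        vectors = [importances]
    else:
        vectors = list(importances.values())
        if not vectors:
            raise ValueError("no importance vectors given")
    chosen = set()
    for iv in vectors:
        chosen.update(iv.above(threshold))
    if not chosen:
        warnings.warn(f"no node exceeds importance threshold {threshold}", stacklevel=2)
        return []
    order = {lab: k for k, lab in enumerate(vectors[0].labels)}
    return sorted(chosen, key=lambda lab: order.get(lab, len(order)))
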