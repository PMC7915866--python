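"""Topology metrics of the binary muscle functional network.

Per-node degree k_i, average degree <k>, degree distribution P(k) = n_k / n,
local clustering C_i = 2 E_i / (k_i (k_i - 1)) with network clustering C the
node mean, and average shortest-path length L = sum_{i!=j} d_ij / (n (n-1))
over unweighted BFS distances.  A six-area electrode map supports per-area
mean-degree profiles across the stump's front, back and side surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from .minet import BinaryNet

__all__ = [
    "NetSummary",
    "AreaMap",
    "DisconnectedError",
    "degree_stats",
    "clustering",
    "avg_path_length",
    "summarize",
    "area_degree_profile",
]


class DisconnectedError(ValueError):
    """Raised for path-based metrics on a disconnected network."""

    def __init__(self, component_sizes: Sequence[int]):
        super().__init__(
            f"network is disconnected (component sizes {sorted(component_sizes, reverse=True)})"
        )
        self.component_sizes = tuple(component_sizes)


@dataclass(frozen=True)
class NetSummary:
    """Bundle of the topology features of one binary network."""

    labels: tuple[str, ...]
    degrees: tuple[int, ...]
    avg_degree: float
    degree_distribution: Mapping[int, float]  # k -> P(k)
    clustering_per_node: tuple[float, ...]
    clustering: float
    path_length: float | None  # None when disconnected
    connected: bool


def degree_stats(net: BinaryNet) -> tuple[np.ndarray, float, dict[int, float]]:
    """Degrees k_i, average degree <k>, and degree distribution P(k)."""
    deg = net.degrees()
    avg = float(deg.mean())
    ks, counts = np.unique(deg, return_counts=True)
    pk = {int(k): float(c) / net.n for k, c in zip(ks, counts)}
    return deg, avg, pk


def clustering(net: BinaryNet) -> tuple[np.ndarray, float]:
    """Local clustering coefficients and their network mean.

    Nodes with degree below 2 have an undefined neighbour-pair ratio and are
    assigned C_i = 0, keeping C a mean over all nodes.
    """
    a = net.adjacency
    deg = net.degrees()
    ci = np.zeros(net.n)
    for i in range(net.n):
        k = deg[i]
        if k < 2:
            continue
        nbrs = np.nonzero(a[i])[0]
        ei = a[np.ix_(nbrs, nbrs)].sum() / 2
        ci[i] = 2.0 * ei / (k * (k - 1))
    return ci, float(ci.mean())


def _distances(net: BinaryNet) -> np.ndarray:
    return shortest_path(net.adjacency, method="D", directed=False, unweighted=True)


def _component_sizes(net: BinaryNet) -> list[int]:
    n_comp, lab = connected_components(net.adjacency, directed=False)
    return [int((lab == c).sum()) for c in range(n_comp)]

def is_connected(net: BinaryNet) -> bool:
    return connected_components(net.adjacency, directed=False)[0] == 1


def avg_path_length(net: BinaryNet) -> float:
    """Mean BFS distance over ordered node pairs; errors if disconnected."""
    if net.n < 2:
        raise ValueError("path length needs at least two nodes")
    d = _distances(net)
    off = ~np.eye(net.n, dtype=bool)
    if not np.isfinite(d[off]).all():
        raise DisconnectedError(_component_sizes(net))
    return float(d[off].mean())


def summarize(net: BinaryNet) -> NetSummary:
    deg, avg, pk = degree_stats(net)
    ci, c = clustering(net)
    connected = is_connected(net)
    lpath = avg_path_length(net) if connected and net.n > 1 else None
    return NetSummary(
        labels=tuple(net.labels),
        degrees=tuple(int(k) for k in deg),
        avg_degree=avg,
        degree_distribution=pk,
        clustering_per_node=tuple(float(x) for x in ci),
        clustering=c,
        path_length=lpath,
        connected=connected,
    )


# ---------------------------------------------------------------------------
# electrode areas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AreaMap:
    """Channel -> electrode area (1-6) and stump surface (front/back/side)."""

    area: Mapping[str, int]
    surface: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.area) != set(self.surface):
            raise ValueError("area and surface maps must cover the same channels")
        for a in set(self.area.values()):
            if not any(v == a for v in self.area.values()):
                raise ValueError(f"area {a} is empty")

    @classmethod
    def default_33(cls) -> "AreaMap":
        """Six areas, two per surface: front V1-V6/V7-V12, back V13-V17/
        V18-V23, side V24-V28/V29-V33.  The split within each surface keeps
        node counts roughly equal; it carries no anatomical claim about
        which half is nearer the wound."""
        blocks = [
            (1, 6, 1, "front"),
            (7, 12, 2, "front"),
            (13, 17, 3, "back"),
            (18, 23, 4, "back"),
            (24, 28, 5, "side"),
            (29, 33, 6, "side"),
        ]
        area: dict[str, int] = {}
        surface: dict[str, str] = {}
        for lo, hi, aid, surf in blocks:
            for i in range(lo, hi + 1):
                area[f"V{i}"] = aid
                surface[f"V{i}"] = surf
        return cls(area=area, surface=surface)

    def channels_in_area(self, area_id: int) -> list[str]:
        return [c for c, a in self.area.items() if a == area_id]


def area_degree_profile(net: BinaryNet, areas: AreaMap) -> pd.DataFrame:
    """Mean node degree per electrode area, plus the overall mean.

    Returns a frame indexed by area id with columns ``surface``,
    ``n_channels`` and ``mean_degree``; the overall mean is the row with
    index 0 and surface ``all``.
    """
    uncovered = [lab for lab in net.labels if lab not in areas.area]
    if uncovered:
        raise ValueError(f"channels not covered by the area map: {uncovered}")
    deg = dict(zip(net.labels, net.degrees()))
    rows = []
    for aid in sorted(set(areas.area.values())):
        chans = [c for c in areas.channels_in_area(aid) if c in deg]
        if not chans:
            continue
        rows.append(
            {
                "area": aid,
                "surface": areas.surface[chans[0]],
                "n_channels": len(chans),
                "mean_degree": float(np.mean([deg[c] for c in chans])),
            }
        )
    rows.append(
        {
            "area": 0,
            "surface": "all",
            "n_channels": net.n,
            "mean_degree": float(np.mean(list(deg.values()))),
        }
    )
    return pd.DataFrame(rows).set_index("area")
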