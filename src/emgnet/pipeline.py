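"""End-to-end orchestration: recordings to sensor selection and report.

One run covers, per movement condition: preprocessing, lift-phase
segmentation, the normalized-MI weighted network, threshold selection (a
single threshold common to all conditions, the largest grid value feasible
for every condition), topology metrics and area profiles, contraction
importance and key-node selection (union across conditions), the key-node
subnetworks, CCM information-flow networks, sensor ranking/selection, the
per-condition feature table (C, <k>, L of the key-node networks) and an
average-linkage clustering of the conditions on standardized features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from . import ccm as _ccm
from . import importance as _importance
from . import minet as _minet
from . import netmetrics as _netmetrics
from .preprocess import preprocess_recording, segment_phase
from .recording import EMGRecording
from .synthetic import SimConfig, TruthRecord, generate_recording

__all__ = [
    "PipelineParams",
    "Report",
    "Dendrogram",
    "run_pipeline",
    "movement_feature_table",
    "cluster_movements",
    "select_common_threshold",
]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable parameters of one end-to-end run."""

    low: float = 20.0
    high: float = 450.0
    order: int = 4
    phase: str = "lift"
    bins: int = 16
    threshold_step: float = 0.01
    importance_threshold: float = 0.5
    ccm_E: int = 4
    ccm_tau: int | None = None
    ccm_lib_sizes: tuple[int, ...] | None = None
    ccm_repeats: int = 3
    n_sensors: int = 5
    k_clusters: int = 2
    seed: int = 0


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge sequence and the partition at k clusters."""

    labels: tuple[str, ...]
    merges: np.ndarray  # scipy linkage matrix
    k: int
    partition: Mapping[str, int]

    def clusters(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for lab, c in self.partition.items():
            out.setdefault(c, set()).add(lab)
        return [out[c] for c in sorted(out)]


@dataclass
class Report:
    """All artifacts of one pipeline run."""

    params: PipelineParams
    conditions: tuple[str, ...]
    truths: dict[str, TruthRecord | None]
    weighted: dict[str, _minet.WeightedNet]
    threshold: float
    threshold_trace: pd.DataFrame
    binary: dict[str, _minet.BinaryNet]
    summaries: dict[str, _netmetrics.NetSummary]
    area_profiles: dict[str, pd.DataFrame]
    importances: dict[str, _importance.ImportanceVector]
    key_nodes: tuple[str, ...]
    key_networks: dict[str, _minet.BinaryNet]
    directed: dict[str, _ccm.DirectedNet]
    overall_directed: _ccm.DirectedNet
    selection: _ccm.SensorSelection
    feature_table: pd.DataFrame
    dendrogram: Dendrogram | None

    def write(self, outdir: str | Path) -> Path:
        """Write the run's tables and networks under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.threshold_trace.to_csv(out / "threshold_trace.csv", index=False)
        self.feature_table.to_csv(out / "feature_table.csv")
        for cond in self.conditions:
            self.weighted[cond].to_frame().to_csv(out / f"weighted_{cond}.csv")
            edges = pd.DataFrame(self.binary[cond].edge_list(), columns=["a", "b"])
            edges.to_csv(out / f"edges_{cond}.csv", index=False)
            self.area_profiles[cond].to_csv(out / f"area_profile_{cond}.csv")
        imp = pd.DataFrame(
            {cond: pd.Series(iv.as_dict()) for cond, iv in self.importances.items()}
        )
        imp.to_csv(out / "importance.csv")
        dir_edges = pd.DataFrame(self.overall_directed.edges)
        dir_edges.to_csv(out / "directed_edges.csv", index=False)
        try:
            import networkx as nx

            nx.write_graphml(self.overall_directed.to_networkx(), out / "directed.graphml")
        except Exception:
            pass
        summary = {
            "threshold": self.threshold,
            "key_nodes": list(self.key_nodes),
            "selected_sensors": list(self.selection.selected),
            "surface_coverage": dict(self.selection.surface_coverage),
            "partition": dict(self.dendrogram.partition) if self.dendrogram else None,
            "seed": self.params.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        return out


def select_common_threshold(
    weighted: Mapping[str, _minet.WeightedNet], step: float = 0.01
) -> tuple[float, pd.DataFrame]:
    """Largest grid threshold feasible for every condition simultaneously."""
    traces = []
    for cond, net in weighted.items():
        try:
            _, trace = _minet.select_threshold(net, step=step)
        except _minet.ThresholdSelectionError as err:
            trace = err.trace
        trace = trace.rename(columns={c: f"{c}_{cond}" for c in trace.columns if c != "threshold"})
        traces.append(trace.set_index("threshold"))
    joined = pd.concat(traces, axis=1)
    feas_cols = [c for c in joined.columns if c.startswith("feasible")]
    joined["feasible_all"] = joined[feas_cols].all(axis=1)
    feasible = joined.index[joined["feasible_all"]]
    if len(feasible) == 0:
        raise _minet.ThresholdSelectionError(
            "no threshold is feasible for all conditions", joined.reset_index()
        )
    return float(feasible.max()), joined.reset_index()


def _keynode_subnet(net: _minet.BinaryNet, keys: Sequence[str]) -> _minet.BinaryNet:
    labs = list(net.labels)
    idx = [labs.index(k) for k in keys]
    sub = net.adjacency[np.ix_(idx, idx)]
    return _minet.BinaryNet(labels=list(keys), adjacency=sub, threshold=net.threshold)


def movement_feature_table(key_networks: Mapping[str, _minet.BinaryNet]) -> pd.DataFrame:
    """Per-condition (C, <k>, L) of the key-node networks.

    A disconnected key-node network gets ``NaN`` path length and is flagged
    in the ``connected`` column rather than aborting the run.
    """
    rows = []
    for cond, net in key_networks.items():
        _, avg, _ = _netmetrics.degree_stats(net)
        _, c = _netmetrics.clustering(net)
        connected = _netmetrics.is_connected(net) and net.n > 1
        lpath = _netmetrics.avg_path_length(net) if connected else float("nan")
        rows.append(
            {"condition": cond, "C": c, "k_avg": avg, "L_path": lpath, "connected": connected}
        )
    return pd.DataFrame(rows).set_index("condition")


def cluster_movements(feature_table: pd.DataFrame, k_clusters: int = 2) -> Dendrogram:
    """Average-linkage Euclidean agglomeration on standardized features.

    Columns are z-scored (constant columns drop out of the distance), so the
    result is invariant to rescaling any feature before standardization.
    """
    feats = feature_table[["C", "k_avg", "L_path"]].astype(float)
    if len(feats) < 2:
        raise ValueError("clustering needs at least two conditions")
    if feats.isna().any().any():
        raise ValueError("feature table contains missing values")
    x = feats.to_numpy()
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    merges = linkage(pdist(z, metric="euclidean"), method="average")
    assignment = fcluster(merges, t=k_clusters, criterion="maxclust")
    partition = dict(zip(feature_table.index, (int(c) for c in assignment)))
    return Dendrogram(labels=tuple(feature_table.index), merges=merges, k=k_clusters, partition=partition)


def run_pipeline(
    conditions: Mapping[str, SimConfig | EMGRecording],
    params: PipelineParams = PipelineParams(),
    areas: _netmetrics.AreaMap | None = None,
    outdir: str | Path | None = None,
) -> Report:
    """Execute the full analysis over one or more movement conditions.

    ``conditions`` maps condition labels either to simulation configs (a
    recording is generated) or to ready recordings.  Stages run in order;
    the first failing stage aborts with its name in the error message.
    Clustering requires at least two conditions and is skipped otherwise.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    if areas is None:
        areas = _netmetrics.AreaMap.default_33()

    recordings: dict[str, EMGRecording] = {}
    truths: dict[str, TruthRecord | None] = {}
    for cond, src in conditions.items():
        if isinstance(src, SimConfig):
            rec, truth = generate_recording(src)
            recordings[cond], truths[cond] = rec, truth
        else:
            recordings[cond], truths[cond] = src, None

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Ctx()

    segments: dict[str, list] = {}
    with stage("preprocess"):
        for cond, rec in recordings.items():
            filtered = preprocess_recording(rec, low=params.low, high=params.high, order=params.order)
            segments[cond] = segment_phase(filtered, params.phase)

    weighted: dict[str, _minet.WeightedNet] = {}
    with stage("mi_network"):
        for cond, segs in segments.items():
            weighted[cond] = _minet.build_mi_matrix(segs, bins=params.bins)

    with stage("threshold"):
        threshold, trace = select_common_threshold(weighted, step=params.threshold_step)
        binary = {cond: _minet.binarize(w, threshold) for cond, w in weighted.items()}

    with stage("metrics"):
        summaries = {cond: _netmetrics.summarize(net) for cond, net in binary.items()}
        profiles = {cond: _netmetrics.area_degree_profile(net, areas) for cond, net in binary.items()}

    with stage("importance"):
        importances = {cond: _importance.node_importance(net) for cond, net in binary.items()}
        key_nodes = tuple(
            _importance.select_key_nodes(importances, threshold=params.importance_threshold)
        )
        if not key_nodes:
            raise ValueError("no key nodes above the importance threshold")

    with stage("key_networks"):
        key_networks = {cond: _keynode_subnet(net, key_nodes) for cond, net in binary.items()}

    with stage("ccm"):
        directed, overall, _diag = _ccm.build_directed_network(
            segments,
            nodes=key_nodes,
            E=params.ccm_E,
            tau=params.ccm_tau,
            lib_sizes=params.ccm_lib_sizes,
            repeats=params.ccm_repeats,
            seed=params.seed,
        )

    with stage("sensor_selection"):
        selection = _ccm.rank_and_select_sensors(overall, areas, m=params.n_sensors)

    with stage("features"):
        table = movement_feature_table(key_networks)

    dendro = None
    if len(conditions) >= 2:
        with stage("clustering"):
            dendro = cluster_movements(table, k_clusters=params.k_clusters)

    report = Report(
        params=params,
        conditions=tuple(conditions),
        truths=truths,
        weighted=weighted,
        threshold=threshold,
        threshold_trace=trace,
        binary=binary,
        summaries=summaries,
        area_profiles=profiles,
        importances=importances,
        key_nodes=key_nodes,
        key_networks=key_networks,
        directed=directed,
        overall_directed=overall,
        selection=selection,
        feature_table=table,
        dendrogram=dendro,
    )
    if outdir is not None:
        report.write(outdir)
    return report
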