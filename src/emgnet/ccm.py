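"""Convergent cross-mapping (CCM) causality and sensor selection.

Given two series x and y from one coupled system, the delay embedding of y,

    y(t) = < y[t], y[t - tau], ..., y[t - (E-1) tau] >,

carries the history of everything that drives y.  Simplex projection
estimates x[t] from the E+1 nearest neighbours of y(t) on the reconstructed
manifold My; the Pearson correlation r between the estimate and x is the
cross-map skill.  If x causally drives y, that skill rises and converges as
the library of manifold points grows — so a high skill of *estimating x
from My* is evidence for the direction x -> y.

Neighbour weights follow the standard simplex rule
w_i proportional to exp(-d_i / d_1) with d_1 the nearest-neighbour distance.
The weighting formula sometimes printed for this estimator reduces to a
ratio that is identically one; ``weights="uniform"`` reproduces that
degenerate (unweighted) variant for comparison.

A four-rule decision table turns the pair of converged skills into a
directed verdict; verdicts over all channel pairs per movement condition
are merged into an information-flow network, from which sensors are ranked
(information sources first) and selected subject to covering every stump
surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .minet import BinaryNet  # noqa: F401  (re-exported convenience)
from .netmetrics import AreaMap
from .preprocess import Segment

__all__ = [
    "Manifold",
    "CCMCurve",
    "CausalVerdict",
    "DirectedNet",
    "SensorSelection",
    "delay_embed",
    "default_delay",
    "envelope",
    "cross_map_skill",
    "convergence_analysis",
    "classify_causality",
    "build_directed_network",
    "rank_and_select_sensors",
]


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Manifold:
    """Delay embedding of one series."""

    E: int
    tau: int
    points: np.ndarray  # (n_points, E)
    times: np.ndarray  # sample index of each point's leading coordinate

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def delay_embed(series, E: int = 3, tau: int = 1) -> Manifold:
    """Embed a series: point t is ``<x[t], x[t-tau], ..., x[t-(E-1)tau]>``.

    Yields ``len(series) - (E-1) tau`` points.  ``E = 1`` degenerates to the
    raw samples.
    """
    x = np.asarray(series, dtype=float).ravel()
    if E < 1 or tau < 1:
        raise ValueError("need E >= 1 and tau >= 1")
    span = (E - 1) * tau
    if x.size <= span + 1:
        raise ValueError(
            f"series of length {x.size} too short to embed: need > {span + 1} samples"
        )
    n_pts = x.size - span
    cols = [x[span - k * tau : span - k * tau + n_pts] for k in range(E)]
    points = np.column_stack(cols)
    times = np.arange(span, x.size)
    return Manifold(E=E, tau=tau, points=points, times=times)


def default_delay(series, rate: float | None = None, max_lag: int | None = None) -> int:
    """Delay from the first local minimum of the autocorrelation.

    The search is capped (default: 50 ms of samples when ``rate`` is given,
    else 50 lags); if no local minimum occurs before the cap, the cap is
    returned.
    """
    x = np.asarray(series, dtype=float).ravel()
    if max_lag is None:
        max_lag = int(round(0.05 * rate)) if rate else 50
    max_lag = max(1, min(max_lag, x.size // 2 - 1))
    x = x - x.mean()
    denom = float((x * x).sum())
    if denom == 0:
        return 1
    acf = np.array([float((x[: x.size - k] * x[k:]).sum()) / denom for k in range(max_lag + 2)])
    for k in range(1, max_lag + 1):
        if acf[k] < acf[k - 1] and acf[k] <= acf[k + 1]:
            return k
    return max_lag


def envelope(series, rate: float, cutoff: float = 10.0, order: int = 4, decimate: int = 20) -> np.ndarray:
    """Rectified low-pass amplitude envelope, decimated.

    Raw 2 kHz EMG carriers are noise-dominated for state-space
    reconstruction; the slow activation envelope is the dynamical variable
    cross-mapping operates on.
    """
    x = np.abs(np.asarray(series, dtype=float).ravel())
    sos = _signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    smooth = _signal.sosfiltfilt(sos, x)
    return smooth[::decimate]


# ---------------------------------------------------------------------------
# cross-map skill
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        warnings.warn("degenerate variance in cross-map estimate; skill set to 0", stacklevel=3)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _simplex_estimates(
    target_vals: np.ndarray,
    my: Manifold,
    lib_idx: np.ndarray,
    theiler: int,
    weights: str,
    pred_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-map estimates of ``target_vals`` at selected manifold points.

    Returns (estimates, valid_mask, pred_idx); points without E+1 usable
    neighbours after Theiler exclusion are masked out.
    """
    E = my.E
    k_need = E + 1
    if pred_idx is None:
        pred_idx = np.arange(my.n_points)
    lib_times = my.times[lib_idx]
    pred_times = my.times[pred_idx]
    tree = cKDTree(my.points[lib_idx])
    # enough neighbours to survive the Theiler exclusion: the window covers
    # 2*theiler+1 sample times, of which a lib_size/n_points fraction are in
    # the library on average; pad generously
    expected_excluded = int(np.ceil(4.0 * (2 * theiler + 1) * len(lib_idx) / my.n_points))
    k_query = min(len(lib_idx), k_need + max(8, expected_excluded))
    dist, nbr = tree.query(my.points[pred_idx], k=k_query)
    if k_query == 1:
        dist = dist[:, None]
        nbr = nbr[:, None]
    # exclude temporally adjacent library points (|t_lib - t| <= theiler)
    t_diff = np.abs(lib_times[nbr] - pred_times[:, None])
    dist = np.where(t_diff <= theiler, np.inf, dist)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k_need]
    d_sel = np.take_along_axis(dist, order, axis=1)
    n_sel = np.take_along_axis(nbr, order, axis=1)
    valid = np.isfinite(d_sel).all(axis=1)

    if weights == "uniform":
        w = np.full_like(d_sel, 1.0 / k_need)
    else:
        d1 = d_sel[:, 0:1]
        safe = np.where(d1 > 0, d1, 1.0)
        w = np.exp(-np.where(np.isfinite(d_sel), d_sel, 0.0) / safe)
        # exact matches: all weight on zero-distance neighbours
        zero_rows = (d1[:, 0] == 0) & valid
        if zero_rows.any():
            w[zero_rows] = (d_sel[zero_rows] == 0).astype(float)
        w /= w.sum(axis=1, keepdims=True)

    vals = target_vals[lib_idx[n_sel]]  # map subset positions back to manifold indices
    est = (w * vals).sum(axis=1)
    return est, valid, pred_idx


def cross_map_skill(
    x,
    y,
    E: int = 3,
    tau: int = 1,
    lib_size: int | None = None,
    repeats: int = 10,
    seed: int | np.random.Generator = 0,
    weights: str = "exp",
    theiler: int | None = None,
    pred_size: int | None = None,
) -> tuple[float, float]:
    """Skill of estimating ``x`` from the delay embedding of ``y``.

    For each of ``repeats`` random libraries of ``lib_size`` manifold
    points, simplex projection predicts x at every embeddable time (or a
    random subsample of ``pred_size`` times, for long series) and the
    Pearson r against the true x is recorded.  Returns (mean r, sd over
    repeats).  High skill here supports the causal direction x -> y.
    """
    if weights not in ("exp", "uniform"):
        raise ValueError(f"unknown weighting {weights!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    my = delay_embed(y, E=E, tau=tau)
    x_aligned = x[my.times]
    if theiler is None:
        theiler = (E - 1) * tau
    if lib_size is None:
        lib_size = my.n_points
    if not 2 <= lib_size <= my.n_points:
        raise ValueError(f"lib_size {lib_size} outside [2, {my.n_points}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pred_idx = None
    if pred_size is not None and pred_size < my.n_points:
        pred_idx = np.sort(rng.choice(my.n_points, size=pred_size, replace=False))
    rs = []
    for _ in range(repeats):
        if lib_size == my.n_points:
            lib_idx = np.arange(my.n_points)
        else:
            lib_idx = rng.choice(my.n_points, size=lib_size, replace=False)
        est, valid, pidx = _simplex_estimates(x_aligned, my, lib_idx, theiler, weights, pred_idx)
        rs.append(_pearson(est[valid], x_aligned[pidx][valid]))
        if lib_size == my.n_points:
            break  # full library (and fixed prediction set) is deterministic
    rs = np.asarray(rs)
    return float(rs.mean()), float(rs.std())


@dataclass(frozen=True)
class CCMCurve:
    """Cross-map skill vs library length, both directions.

    ``skill_x_from_my`` is the skill of estimating x from y's manifold
    (evidence for x -> y); ``skill_y_from_mx`` the reverse.
    """

    lib_sizes: tuple[int, ...]
    skill_x_from_my: tuple[float, ...]
    sd_x_from_my: tuple[float, ...]
    skill_y_from_mx: tuple[float, ...]
    sd_y_from_mx: tuple[float, ...]
    repeats: int
    seed: int
    trend_x_from_my: float
    trend_y_from_mx: float

    @property
    def mx_skill(self) -> float:
        """Converged skill of estimating x from My (supports x -> y)."""
        return self.skill_x_from_my[-1]

    @property
    def my_skill(self) -> float:
        """Converged skill of estimating y from Mx (supports y -> x)."""
        return self.skill_y_from_mx[-1]


def _trend(lib_sizes: Sequence[int], skills: Sequence[float]) -> float:
    if len(lib_sizes) < 3 or len(set(skills)) < 2:
        return 0.0
    rho = spearmanr(lib_sizes, skills).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def convergence_analysis(
    x,
    y,
    E: int = 3,
    tau: int = 1,
    lib_sizes: Sequence[int] | None = None,
    repeats: int = 10,
    seed: int = 0,
    weights: str = "exp",
    pred_size: int | None = None,
) -> CCMCurve:
    """Cross-map skill at each library length, in both directions.

    Convergence — skill increasing and levelling off with library length —
    is summarized by the Spearman correlation of mean skill against library
    length; the converged skills are the means at the largest library.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    max_pts = x.size - (E - 1) * tau
    if lib_sizes is None:
        lo = max(E + 2, 10)
        lib_sizes = sorted({max(lo, int(round(f * max_pts))) for f in (0.1, 0.25, 0.5, 1.0)})
    lib_sizes = list(lib_sizes)
    if lib_sizes != sorted(lib_sizes):
        raise ValueError("lib_sizes must be ascending")
    if lib_sizes[-1] > max_pts:
        raise ValueError(f"largest library {lib_sizes[-1]} exceeds available points {max_pts}")

    rng = np.random.default_rng(seed)
    fwd_m, fwd_s, rev_m, rev_s = [], [], [], []
    for L in lib_sizes:
        m, s = cross_map_skill(
            x, y, E=E, tau=tau, lib_size=L, repeats=repeats, seed=rng,
            weights=weights, pred_size=pred_size,
        )
        fwd_m.append(m)
        fwd_s.append(s)
        m, s = cross_map_skill(
            y, x, E=E, tau=tau, lib_size=L, repeats=repeats, seed=rng,
            weights=weights, pred_size=pred_size,
        )
        rev_m.append(m)
        rev_s.append(s)
    return CCMCurve(
        lib_sizes=tuple(lib_sizes),
        skill_x_from_my=tuple(fwd_m),
        sd_x_from_my=tuple(fwd_s),
        skill_y_from_mx=tuple(rev_m),
        sd_y_from_mx=tuple(rev_s),
        repeats=repeats,
        seed=seed,
        trend_x_from_my=_trend(lib_sizes, fwd_m),
        trend_y_from_mx=_trend(lib_sizes, rev_m),
    )


# ---------------------------------------------------------------------------
# causality classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CausalVerdict:
    """Rule-based causality call from a pair of converged skills."""

    direction: str  # "x_to_y" | "y_to_x" | "none"
    rule: int  # which of the four rules fired
    mx_skill: float
    my_skill: float


def _one_way(a: float, b: float, d_low: float, d_high: float, skill_cut: float) -> tuple[bool, int]:
    """Does the skill pair (a, b) support a causal arrow in a's direction?

    Boundary conventions: D = d_low falls to rule 2 (no causality),
    D = d_high falls to rules 3/4, and a = skill_cut falls to rule 3.
    """
    d = a - b
    if d > d_high:
        return True, 1
    if d <= d_low:
        return False, 2
    if a >= skill_cut:
        return False, 3
    return True, 4


def classify_causality(
    mx_skill: float,
    my_skill: float,
    d_low: float = 0.1,
    d_high: float = 0.3,
    skill_cut: float = 0.5,
) -> CausalVerdict:
    """Four-rule decision table on the converged skill difference D = Mx - My.

    1. D > 0.3: one-way causality x -> y.
    2. D < 0.1: skills similar, no one-way causality.
    3. 0.1 < D < 0.3 with Mx > 0.5: no one-way causality.
    4. 0.1 < D < 0.3 with Mx < 0.5: one-way causality x -> y.

    The mirrored test with the arguments swapped decides y -> x, making the
    classifier antisymmetric.  Note rules 3/4 reward the *lower* Mx with a
    causal call — implemented exactly as stated, counterintuitive as it is.
    """
    for v in (mx_skill, my_skill):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"skill {v} outside [-1, 1]")
    fired, rule = _one_way(mx_skill, my_skill, d_low, d_high, skill_cut)
    if fired:
        return CausalVerdict("x_to_y", rule, mx_skill, my_skill)
    fired_rev, rule_rev = _one_way(my_skill, mx_skill, d_low, d_high, skill_cut)
    if fired_rev:
        return CausalVerdict("y_to_x", rule_rev, mx_skill, my_skill)
    return CausalVerdict("none", rule, mx_skill, my_skill)


# ---------------------------------------------------------------------------
# directed network and sensor selection
# ---------------------------------------------------------------------------


@dataclass
class DirectedNet:
    """Information-flow network: arcs point from cause to effect."""

    nodes: tuple[str, ...]
    edges: list[dict] = field(default_factory=list)  # src, dst, condition, rule, bidirectional

    def add_edge(self, src: str, dst: str, condition: str | None, rule: int) -> None:
        if src == dst:
            raise ValueError("self-edges are not allowed")
        self.edges.append(
            {"src": src, "dst": dst, "condition": condition, "rule": rule, "bidirectional": False}
        )

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e["src"], e["dst"]) for e in self.edges}

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e["src"], e["dst"])
        return g


def combine_directed(nets: Mapping[str, DirectedNet]) -> DirectedNet:
    """Union of per-condition information-flow networks.

    An arc present in both orientations (across conditions) is flagged
    bidirectional on both entries.
    """
    all_nodes: list[str] = []
    for net in nets.values():
        for nd in net.nodes:
            if nd not in all_nodes:
                all_nodes.append(nd)
    overall = DirectedNet(nodes=tuple(all_nodes))
    seen: set[tuple[str, str]] = set()
    for net in nets.values():
        for e in net.edges:
            key = (e["src"], e["dst"])
            if key in seen:
                continue
            seen.add(key)
            overall.edges.append(dict(e))
    pairs = {(e["src"], e["dst"]) for e in overall.edges}
    for e in overall.edges:
        if (e["dst"], e["src"]) in pairs:
            e["bidirectional"] = True
    return overall


def _profile_normalize(stack: np.ndarray) -> np.ndarray:
    """Divide each repetition's envelope by the time-locked mean profile.

    Every channel's envelope carries the same deterministic movement-phase
    profile (the lift ramp), which would let any two channels cross-map each
    other trivially.  Dividing by the across-repetition mean envelope at
    each within-phase time cancels that shared profile and leaves the
    per-repetition modulation dynamics that causal analysis should see.
    """
    profile = stack.mean(axis=0)
    floor = 0.05 * profile.max()
    profile = np.maximum(profile, floor if floor > 0 else 1.0)
    return stack / profile - 1.0


#: analysis band (Hz) for carrier-mode cross-mapping; deterministic carrier
#: dynamics, where present, are sought inside this sub-band of the EMG band
CARRIER_CCM_BAND = (50.0, 320.0)


def self_normalized_carrier(
    series,
    rate: float,
    band: tuple[float, float] | None = CARRIER_CCM_BAND,
    cutoff: float = 6.0,
    order: int = 4,
) -> np.ndarray:
    """Band-limit a signal and divide it by its own slow amplitude envelope.

    The normalization removes the movement-phase profile and the slow
    activation modulation (below ``cutoff``) while leaving the carrier
    dynamics — the scale on which state-space reconstruction operates —
    untouched.  ``band=None`` skips the band-pass.
    """
    x = np.asarray(series, dtype=float).ravel()
    if band is not None:
        sos_b = _signal.butter(4, band, btype="band", fs=rate, output="sos")
        x = _signal.sosfiltfilt(sos_b, x)
    sos = _signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    env = _signal.sosfiltfilt(sos, np.abs(x))
    floor = 0.05 * env.max()
    return x / np.maximum(env, floor if floor > 0 else 1.0)


def build_directed_network(
    segments_by_condition: Mapping[str, Sequence[Segment]],
    nodes: Sequence[str],
    E: int = 3,
    tau: int | None = None,
    lib_sizes: Sequence[int] | None = None,
    repeats: int = 5,
    seed: int = 0,
    mode: str = "carrier",
    envelope_cutoff: float = 10.0,
    decimate: int = 20,
    pred_size: int | None = 1200,
    min_skill: float = 0.2,
) -> tuple[dict[str, DirectedNet], DirectedNet, dict]:
    """CCM over all node pairs per condition; union into an overall network.

    ``mode`` selects the per-channel series fed to cross-mapping:

    * ``"carrier"`` (default): the filtered signal divided by its own slow
      amplitude envelope, at full rate.  Amplitude-envelope estimates of a
      stochastic carrier are too noisy for state-space reconstruction at
      these recording lengths, so causality is sought in the carrier
      dynamics themselves.
    * ``"envelope"``: rectified low-pass envelopes, decimated and
      normalized by the across-repetition mean profile.
    * ``"raw"``: the filtered signal as-is.

    Returns (per-condition nets, overall net, diagnostics with the CCM
    curves per pair and condition).
    """
    if mode not in ("carrier", "envelope", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    if not segments_by_condition:
        raise ValueError("need at least one condition")
    nodes = list(nodes)
    pernet: dict[str, DirectedNet] = {}
    curves: dict[tuple[str, str, str], CCMCurve] = {}
    rng = np.random.default_rng(seed)
    for cond, segments in segments_by_condition.items():
        if not segments:
            raise ValueError(f"condition {cond!r} has no segments")
        labels = list(segments[0].labels)
        missing = [n for n in nodes if n not in labels]
        if missing:
            raise ValueError(f"nodes {missing} absent from condition {cond!r}")
        rate = segments[0].rate
        series: dict[str, np.ndarray] = {}
        for lab in nodes:
            j = labels.index(lab)
            if mode == "envelope":
                parts = [
                    envelope(seg.data[:, j], seg.rate, cutoff=envelope_cutoff, decimate=decimate)
                    for seg in segments
                ]
                if len(parts) > 1 and len({p.size for p in parts}) == 1:
                    parts = list(_profile_normalize(np.vstack(parts)))
            elif mode == "carrier":
                sos_b = _signal.butter(4, CARRIER_CCM_BAND, btype="band", fs=rate, output="sos")
                parts = [_signal.sosfiltfilt(sos_b, seg.data[:, j]) for seg in segments]
                if len(parts) > 1 and len({p.size for p in parts}) == 1:
                    # repetition-locked amplitude profile: a deterministic
                    # divisor that removes the movement-phase envelope
                    # without imprinting per-repetition stochastic noise
                    stack = np.vstack(parts)
                    sos_l = _signal.butter(4, 6.0, btype="low", fs=rate, output="sos")
                    prof = _signal.sosfiltfilt(sos_l, np.abs(stack).mean(axis=0))
                    prof = np.maximum(prof, 0.1 * prof.max()) if prof.max() > 0 else 1.0
                    parts = list(stack / prof)
                else:
                    parts = [self_normalized_carrier(p, rate, band=None) for p in parts]
            else:
                parts = [seg.data[:, j] for seg in segments]
            series[lab] = np.concatenate(parts)
        rate_eff = rate / (decimate if mode == "envelope" else 1)
        if tau is None:
            node_tau = {lab: default_delay(series[lab], rate=rate_eff) for lab in nodes}
        else:
            node_tau = {lab: tau for lab in nodes}
        tau_c = max(1, int(np.median(list(node_tau.values()))))
        n_pts = len(next(iter(series.values()))) - (E - 1) * max(node_tau.values())
        if lib_sizes is None:
            caps = (500, 1500, 4000) if mode != "envelope" else (100, 300, 900)
            libs = sorted({min(c, n_pts) for c in caps} | {n_pts if mode == "envelope" else min(4000, n_pts)})
            libs = [L for L in libs if L >= E + 2]
        else:
            libs = [L for L in lib_sizes if L <= n_pts]
        net = DirectedNet(nodes=tuple(nodes))
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                pair_seed = int(rng.integers(0, 2**31 - 1))
                tau_pair = max(node_tau[a], node_tau[b])
                curve = convergence_analysis(
                    series[a], series[b], E=E, tau=tau_pair, lib_sizes=libs,
                    repeats=repeats, seed=pair_seed, pred_size=pred_size,
                )
                verdict = classify_causality(curve.mx_skill, curve.my_skill)
                curves[(cond, a, b)] = curve
                # the decision rules presuppose skills that have converged to
                # a meaningfully positive value; do not call causality when
                # neither direction ever rises above the floor
                if max(curve.mx_skill, curve.my_skill) < min_skill:
                    continue
                if verdict.direction == "x_to_y":
                    net.add_edge(a, b, cond, verdict.rule)
                elif verdict.direction == "y_to_x":
                    net.add_edge(b, a, cond, verdict.rule)
        pernet[cond] = net
    overall = combine_directed(pernet)
    return pernet, overall, {"curves": curves, "tau": tau_c, "lib_sizes": libs, "mode": mode}


@dataclass(frozen=True)
class SensorSelection:
    """Ranked sensor labels and the selected, surface-covering subset."""

    ranked: tuple[str, ...]
    ranks: Mapping[str, int]  # ties share a rank
    selected: tuple[str, ...]
    surface_coverage: Mapping[str, int]
    swaps: tuple[str, ...] = ()


def _label_key(label: str):
    if label.startswith("V") and label[1:].isdigit():
        return (0, int(label[1:]))
    return (1, label)


def rank_and_select_sensors(dnet: DirectedNet, areas: AreaMap, m: int = 5) -> SensorSelection:
    """Rank nodes information-sources-first and pick a surface-covering top-m.

    The rank key per node is (longest directed path from any source ending
    at the node — ascending, so pure sources come first; then out-degree
    minus in-degree, descending; then label order).  On a cyclic network the
    depth is computed on the condensation of strongly connected components,
    whose members share a depth.  The top-m set is then minimally adjusted
    so that every stump surface with at least one candidate node is
    represented.
    """
    import networkx as nx

    if m < 1:
        raise ValueError("m must be >= 1")
    g = dnet.to_networkx()
    cond = nx.condensation(g)
    depth: dict[int, int] = {}
    for scc in nx.topological_sort(cond):
        preds = list(cond.predecessors(scc))
        depth[scc] = 0 if not preds else 1 + max(depth[p] for p in preds)
    node_depth = {n: depth[cond.graph["mapping"][n]] for n in g.nodes}
    flow = {n: g.out_degree(n) - g.in_degree(n) for n in g.nodes}

    def key(n: str):
        return (node_depth[n], -flow[n], _label_key(n))

    ranked = sorted(g.nodes, key=key)
    ranks: dict[str, int] = {}
    for pos, n in enumerate(ranked):
        if pos > 0 and key(n)[:2] == key(ranked[pos - 1])[:2]:
            ranks[n] = ranks[ranked[pos - 1]]  # ties share a rank
        else:
            ranks[n] = pos + 1

    surface = {n: areas.surface.get(n, "unknown") for n in ranked}
    selected = list(ranked[:m])
    swaps: list[str] = []
    all_surfaces = {surface[n] for n in ranked}
    for surf in sorted(all_surfaces):
        if surf in {surface[n] for n in selected}:
            continue
        candidate = next(n for n in ranked if surface[n] == surf)
        # drop the worst-ranked selected node whose surface stays represented
        for victim in reversed(selected):
            remaining = [surface[n] for n in selected if n is not victim]
            if surface[victim] in remaining:
                selected.remove(victim)
                selected.append(candidate)
                selected.sort(key=key)
                swaps.append(f"{victim}->{candidate}")
                break
    coverage: dict[str, int] = {}
    for n in selected:
        coverage[surface[n]] = coverage.get(surface[n], 0) + 1
    return SensorSelection(
        ranked=tuple(ranked),
        ranks=ranks,
        selected=tuple(selected),
        surface_coverage=coverage,
        swaps=tuple(swaps),
    )
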