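"""Delay embedding, cross-map skill, causality rules and sensor selection."""

import numpy as np
import pytest

from emgnet.ccm import (
    DirectedNet,
    classify_causality,
    combine_directed,
    convergence_analysis,
    cross_map_skill,
    default_delay,
    delay_embed,
    rank_and_select_sensors,
)
from emgnet.netmetrics import AreaMap
from emgnet.synthetic import CouplingSpec, generate_coupled_logistic


class TestDelayEmbedding:
    def test_point_count_formula(self):
        m = delay_embed(np.arange(10.0), E=2, tau=1)
        assert m.n_points == 9

    def test_degenerate_embedding_is_raw_series(self):
        x = np.arange(7.0)
        m = delay_embed(x, E=1, tau=3)
        assert np.array_equal(m.points.ravel(), x)

    def test_ramp_alignment(self):
        m = delay_embed(np.arange(10.0), E=3, tau=2)
        assert np.array_equal(m.points[0], [4.0, 2.0, 0.0])
        assert m.n_points == 6

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            delay_embed(np.arange(5.0), E=3, tau=3)

    def test_default_delay_of_sinusoid_near_quarter_period(self):
        t = np.arange(2000)
        x = np.sin(2 * np.pi * t / 40)  # period 40 samples
        tau = default_delay(x, max_lag=30)
        assert 15 <= tau <= 25  # first ACF minimum is the half period


class TestCrossMapSkill:
    def test_identical_series_reach_unit_skill(self):
        x, _ = generate_coupled_logistic(CouplingSpec(beta_yx=0.0, seed=1))
        r, _ = cross_map_skill(x, x, E=3, tau=1)
        assert r >= 0.99

    def test_independent_noise_has_no_skill(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(1000), rng.standard_normal(1000)
        r, _ = cross_map_skill(a, b, E=3, tau=1, lib_size=900, repeats=10, seed=1)
        assert abs(r) < 0.1

    def test_driver_recoverable_from_driven_manifold(self):
        # x drives y: estimating x from y's manifold must beat the reverse
        x, y = generate_coupled_logistic(CouplingSpec(seed=3))
        fwd, _ = cross_map_skill(x, y, E=3, tau=1, lib_size=900, repeats=5, seed=1)
        rev, _ = cross_map_skill(y, x, E=3, tau=1, lib_size=900, repeats=5, seed=1)
        assert fwd > rev

    def test_constant_series_warns_and_scores_zero(self):
        x = np.zeros(200)
        y = np.sin(np.arange(200.0))
        with pytest.warns(UserWarning):
            r, _ = cross_map_skill(x, y, E=2, tau=1, repeats=1)
        assert r == 0.0

    def test_uniform_weight_variant_runs(self):
        x, y = generate_coupled_logistic(CouplingSpec(seed=4, length=500))
        r, _ = cross_map_skill(x, y, E=3, tau=1, weights="uniform", repeats=1)
        assert -1.0 <= r <= 1.0


class TestConvergence:
    def test_identical_series_converged_everywhere(self):
        x, _ = generate_coupled_logistic(CouplingSpec(beta_yx=0.0, seed=5))
        curve = convergence_analysis(x, x, E=3, tau=1, lib_sizes=[100, 400, 900], repeats=3, seed=1)
        assert min(curve.skill_x_from_my) > 0.95

    def test_skill_grows_with_library_in_true_direction(self):
        x, y = generate_coupled_logistic(CouplingSpec(seed=6))
        curve = convergence_analysis(
            x, y, E=3, tau=1, lib_sizes=[100, 200, 400, 700, 900], repeats=5, seed=1
        )
        assert curve.trend_x_from_my > 0
        assert curve.mx_skill > curve.skill_x_from_my[0]

    def test_independent_pair_converges_to_nothing(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(1000), rng.standard_normal(1000)
        curve = convergence_analysis(a, b, E=3, tau=1, lib_sizes=[100, 400, 900], repeats=5, seed=1)
        assert abs(curve.mx_skill) < 0.1 and abs(curve.my_skill) < 0.1
        verdict = classify_causality(curve.mx_skill, curve.my_skill)
        assert verdict.direction == "none"


class TestCausalityRules:
    @pytest.mark.parametrize(
        "mx,my,direction,rule",
        [
            (0.90, 0.50, "x_to_y", 1),
            (0.60, 0.55, "none", 2),
            (0.45, 0.25, "x_to_y", 4),
            (0.70, 0.50, "none", 3),
            (0.50, 0.90, "y_to_x", 1),
            (0.25, 0.45, "y_to_x", 4),
        ],
    )
    def test_printed_rule_examples(self, mx, my, direction, rule):
        v = classify_causality(mx, my)
        assert (v.direction, v.rule) == (direction, rule)

    def test_boundary_conventions(self):
        # D = 0.1 falls to rule 2; D = 0.3 to rules 3/4; Mx = 0.5 to rule 3
        assert classify_causality(0.6, 0.5).rule == 2
        assert classify_causality(0.3, 0.0).direction == "x_to_y"  # D=0.3, mx<0.5
        assert classify_causality(0.3, 0.0).rule == 4
        assert classify_causality(0.5, 0.3).rule == 3  # mx exactly at the cut

    def test_antisymmetry_over_grid(self):
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
        for a in grid:
            for b in grid:
                va = classify_causality(a, b)
                vb = classify_causality(b, a)
                if va.direction == "x_to_y":
                    assert vb.direction == "y_to_x"
                elif va.direction == "y_to_x":
                    assert vb.direction == "x_to_y"
                else:
                    assert vb.direction == "none"

    def test_skills_outside_range_rejected(self):
        with pytest.raises(ValueError):
            classify_causality(1.2, 0.0)


class TestDirectedNetAssembly:
    def test_no_self_edges(self):
        net = DirectedNet(nodes=("a", "b"))
        with pytest.raises(ValueError):
            net.add_edge("a", "a", None, 1)

    def test_union_flags_bidirectional_across_conditions(self):
        n1 = DirectedNet(nodes=("a", "b"))
        n1.add_edge("a", "b", "c1", 1)
        n2 = DirectedNet(nodes=("a", "b"))
        n2.add_edge("b", "a", "c2", 1)
        overall = combine_directed({"c1": n1, "c2": n2})
        assert all(e["bidirectional"] for e in overall.edges)
        assert overall.edge_pairs() == {("a", "b"), ("b", "a")}


def area_map_for(nodes_surfaces):
    area = {}
    surface = {}
    area_ids = {"front": 1, "back": 3, "side": 5}
    for node, surf in nodes_surfaces.items():
        area[node] = area_ids[surf]
        surface[node] = surf
    return AreaMap(area=area, surface=surface)


class TestSensorSelection:
    def test_hub_of_out_edges_selected_first(self):
        net = DirectedNet(nodes=("h", "a", "b", "c"))
        for t in ("a", "b", "c"):
            net.add_edge("h", t, None, 1)
        amap = area_map_for({"h": "side", "a": "front", "b": "back", "c": "front"})
        sel = rank_and_select_sensors(net, amap, m=1)
        assert sel.ranked[0] == "h"
        assert "h" in sel.selected

    def test_chain_ranks_sources_first(self):
        net = DirectedNet(nodes=("a", "b", "c"))
        net.add_edge("a", "b", None, 1)
        net.add_edge("b", "c", None, 1)
        amap = area_map_for({"a": "front", "b": "front", "c": "front"})
        sel = rank_and_select_sensors(net, amap, m=2)
        assert set(sel.selected) == {"a", "b"}
        assert sel.ranked == ("a", "b", "c")

    def test_missing_surface_swapped_in(self):
        # two front sources outrank the only back candidate; top-2 must
        # still cover the back surface
        net = DirectedNet(nodes=("f1", "f2", "k1"))
        net.add_edge("f1", "k1", None, 1)
        net.add_edge("f2", "k1", None, 1)
        amap = area_map_for({"f1": "front", "f2": "front", "k1": "back"})
        sel = rank_and_select_sensors(net, amap, m=2)
        assert "k1" in sel.selected
        assert len(sel.swaps) == 1

    def test_cycle_members_share_rank(self):
        net = DirectedNet(nodes=("a", "b", "c"))
        net.add_edge("a", "b", None, 1)
        net.add_edge("b", "a", None, 1)
        net.add_edge("a", "c", None, 1)
        amap = area_map_for({"a": "front", "b": "front", "c": "back"})
        sel = rank_and_select_sensors(net, amap, m=3)
        # a, b form one strongly connected component at depth 0 but differ
        # in net flow; c is downstream of it
        assert sel.ranked[-1] == "c"

    def test_ties_share_a_rank(self):
        net = DirectedNet(nodes=("a", "b", "c"))
        amap = area_map_for({"a": "front", "b": "front", "c": "front"})
        sel = rank_and_select_sensors(net, amap, m=2)
        assert len(set(sel.ranks.values())) == 1  # all isolated, all tied


class TestClassifierProperties:
    from hypothesis import given, settings, strategies as st

    skill = st.floats(min_value=-1.0, max_value=1.0, allow_nan=False)

    @given(a=skill, b=skill)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_antisymmetry_everywhere(self, a, b):
        va = classify_causality(a, b)
        vb = classify_causality(b, a)
        flip = {"x_to_y": "y_to_x", "y_to_x": "x_to_y", "none": "none"}
        assert vb.direction == flip[va.direction]
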