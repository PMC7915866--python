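"""Histogram entropies, mutual information and network thresholding."""

import numpy as np
import pytest

from _oracles import symbol_entropy, symbol_joint_entropy, symbol_mutual_information
from emgnet.minet import (
    ThresholdSelectionError,
    WeightedNet,
    binarize,
    build_mi_matrix,
    channel_entropy,
    joint_entropy,
    mutual_information,
    normalized_mutual_information,
    select_threshold,
)
from emgnet.preprocess import Segment, preprocess_recording, segment_phase


def integer_series(rng, n, n_symbols):
    return rng.integers(0, n_symbols, size=n).astype(float)


class TestEntropy:
    def test_two_symbol_alternation_is_one_bit(self):
        series = np.tile([0.0, 1.0], 500)
        assert channel_entropy(series, bins=2) == pytest.approx(1.0)

    def test_constant_series_has_zero_entropy(self):
        assert channel_entropy(np.full(100, 3.7), bins=8) == 0.0

    def test_uniform_random_entropy_near_log2_bins(self):
        rng = np.random.default_rng(0)
        h = channel_entropy(rng.uniform(size=1000), bins=16)
        assert 3.9 <= h <= 4.0  # log2(16) = 4 minus finite-sample bias

    def test_empty_and_short_series_rejected(self):
        with pytest.raises(ValueError):
            channel_entropy(np.array([]), bins=4)
        with pytest.raises(ValueError):
            channel_entropy(np.arange(3.0), bins=8)


class TestJointEntropy:
    def test_identical_series_joint_equals_marginal(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=500)
        assert joint_entropy(s, s, bins=8) == pytest.approx(channel_entropy(s, bins=8))

    def test_independent_binary_joint_tends_to_two_bits(self):
        rng = np.random.default_rng(2)
        s = rng.integers(0, 2, 4000).astype(float)
        q = rng.integers(0, 2, 4000).astype(float)
        assert joint_entropy(s, q, bins=2) == pytest.approx(2.0, abs=0.01)

    def test_joint_bounded_by_marginals(self):
        rng = np.random.default_rng(3)
        s, q = rng.normal(size=300), rng.normal(size=300)
        hs, hq = channel_entropy(s, 8), channel_entropy(q, 8)
        hj = joint_entropy(s, q, 8)
        assert max(hs, hq) <= hj + 1e-12
        assert hj <= hs + hq + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_entropy(np.zeros(10) + np.arange(10), np.arange(9), bins=2)


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=400)
        assert mutual_information(s, s, 8) == pytest.approx(channel_entropy(s, 8))

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        s, q = rng.normal(size=400), rng.normal(size=400)
        assert mutual_information(s, q, 8) == pytest.approx(mutual_information(q, s, 8))

    def test_independent_series_mi_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s, q = rng.normal(size=3000), rng.normal(size=3000)
            vals.append(mutual_information(s, q, 16))
        assert np.mean(vals) < 0.05

    @pytest.mark.parametrize("n_symbols", [2, 4, 7])
    def test_exact_match_to_symbol_counting_oracle(self, n_symbols):
        # integer-valued series where every symbol occupies its own bin
        rng = np.random.default_rng(6)
        a = integer_series(rng, 500, n_symbols)
        b = np.where(rng.uniform(size=500) < 0.5, a, integer_series(rng, 500, n_symbols))
        assert channel_entropy(a, n_symbols) == pytest.approx(symbol_entropy(list(a)), abs=1e-12)
        assert joint_entropy(a, b, n_symbols) == pytest.approx(
            symbol_joint_entropy(list(a), list(b)), abs=1e-12
        )
        assert mutual_information(a, b, n_symbols) == pytest.approx(
            symbol_mutual_information(list(a), list(b)), abs=1e-12
        )

    def test_cross_check_against_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        a = integer_series(rng, 800, 5)
        b = np.where(rng.uniform(size=800) < 0.6, a, integer_series(rng, 800, 5))
        ours = mutual_information(a, b, 5)
        theirs = sklearn_metrics.mutual_info_score(a, b) / np.log(2)  # nats -> bits
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestNormalizedMI:
    def test_identical_channels_score_one(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=500)
        assert normalized_mutual_information(s, s, 8) == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            s, q = rng.normal(size=200), rng.normal(size=200)
            v = normalized_mutual_information(s, q, 8)
            assert 0.0 <= v <= 1.0

    def test_constant_channel_scores_zero(self):
        rng = np.random.default_rng(10)
        assert normalized_mutual_information(np.ones(100), rng.normal(size=100), 4) == 0.0


class TestBuildMatrix:
    def test_shape_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(11)
        seg = Segment(rng.normal(size=(300, 3)), 100.0, ["V1", "V2", "V3"], None, 0, "lift")
        net = build_mi_matrix([seg], bins=8)
        assert net.weights.shape == (3, 3)
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)

    def test_identical_channels_give_unit_weight(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=400)
        seg = Segment(np.column_stack([x, x]), 100.0, ["V1", "V2"], None, 0, "lift")
        assert build_mi_matrix([seg], bins=8).weights[0, 1] == pytest.approx(1.0)

    def test_planted_groups_recovered(self, two_group_recording):
        rec, truth = two_group_recording
        segs = segment_phase(preprocess_recording(rec), "lift")
        frame = build_mi_matrix(segs).to_frame()
        within, between = [], []
        labs = list(frame.index)
        for i, a in enumerate(labs):
            for b in labs[i + 1 :]:
                (within if truth.true_groups[a] == truth.true_groups[b] else between).append(
                    frame.loc[a, b]
                )
        assert np.mean(within) > np.mean(between)

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(13)
        s1 = Segment(rng.normal(size=(100, 2)), 10.0, ["V1", "V2"], None, 0, "lift")
        s2 = Segment(rng.normal(size=(100, 2)), 10.0, ["V1", "V3"], None, 1, "lift")
        with pytest.raises(ValueError):
            build_mi_matrix([s1, s2])


class TestThreshold:
    def test_binarize_extremes(self):
        w = WeightedNet(["a", "b", "c"], np.array([[0, 0.4, 0.6], [0.4, 0, 0.6], [0.6, 0.6, 0]]))
        assert binarize(w, 0.0).n_edges == 3
        assert binarize(w, 1.0).n_edges == 0
        mid = binarize(w, 0.55)
        assert set(mid.edge_list()) == {("a", "c"), ("b", "c")}

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(14)
        m = rng.uniform(size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        w = WeightedNet([f"V{i}" for i in range(8)], m)
        counts = [binarize(w, th).n_edges for th in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_uniform_complete_graph_selects_just_below_weight(self):
        n = 20  # needs n-1 > 2 ln n
        m = np.full((n, n), 0.7)
        np.fill_diagonal(m, 0)
        w = WeightedNet([f"V{i}" for i in range(n)], m)
        th, trace = select_threshold(w, step=0.01)
        assert th == pytest.approx(0.69)
        assert trace.loc[trace["threshold"] == 0.69, "feasible"].item()

    def test_no_feasible_threshold_raises_with_trace(self):
        # two dense cliques, no inter-clique weight: never connected
        m = np.zeros((8, 8))
        m[:4, :4] = 0.9
        m[4:, 4:] = 0.9
        np.fill_diagonal(m, 0)
        w = WeightedNet([f"V{i}" for i in range(8)], m)
        with pytest.raises(ThresholdSelectionError) as err:
            select_threshold(w)
        assert not err.value.trace["feasible"].any()


class TestEntropyProperties:
    """Property-based invariants of the histogram estimators."""

    from hypothesis import given, settings, strategies as st

    finite_series = st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=16, max_size=200
    )

    @given(xs=finite_series)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_entropy_bounded_by_log_bins(self, xs):
        h = channel_entropy(np.array(xs), bins=16)
        assert 0.0 <= h <= 4.0 + 1e-9

    @given(xs=finite_series, ys=finite_series)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_mi_nonnegative_and_bounded(self, xs, ys):
        n = min(len(xs), len(ys))
        a, b = np.array(xs[:n]), np.array(ys[:n])
        mi = mutual_information(a, b, bins=8)
        assert mi >= 0.0
        assert mi <= min(channel_entropy(a, 8), channel_entropy(b, 8)) + 1e-9
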