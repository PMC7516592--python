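"""Wave intervals and the law of maximum uncertainty prediction."""

import itertools
import math

import numpy as np
import pytest

from qlbn import (
    PrincipleDispatchError,
    WaveInterval,
    binary_entropy,
    build_balance_system,
    build_wave,
    decompose_query,
    entropy_principle,
    evaluate_wave,
    intervals_overlap,
    mirror_principle,
    predict_max_uncertainty,
    quarter_law,
    wave_interval,
)
from conftest import make_two_node


def waves_for(net, query="Y", yes="y", no="not_y"):
    w_yes = build_wave(decompose_query(net, query, yes))
    w_no = build_wave(decompose_query(net, query, no))
    return w_yes, w_no


class TestScalars:
    @pytest.mark.parametrize(
        "p, expected", [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0), (0.25, 0.8113)]
    )
    def test_binary_entropy(self, p, expected):
        assert binary_entropy(p) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "classical, expected", [(0.95, 0.70), (0.54, 0.29), (0.10, 0.0)]
    )
    def test_quarter_law(self, classical, expected):
        assert quarter_law(classical).value == pytest.approx(expected, abs=1e-12)


class TestIntervals:
    @pytest.mark.parametrize(
        "p1, p2, lo, hi",
        [
            (0.84, 0.97, 0.84, 0.97),  # PD (a), defection wave
            (0.77, 0.82, 0.59, 1.00),  # PD (b)
            (0.93, 0.97, 0.90, 1.00),  # PD (d)
        ],
    )
    def test_pd_defection_intervals(self, p1, p2, lo, hi):
        net = make_two_node(1 - p1, 1 - p2)  # y = cooperate, not_y = defect
        w_y, w_n = waves_for(net)
        iv = wave_interval(w_n, w_y)
        assert round(iv.lo + 1e-12, 2) == pytest.approx(lo)
        assert round(iv.hi + 1e-12, 2) == pytest.approx(hi)

    def test_three_configuration_minimum(self, m3_net):
        w_y, w_n = waves_for(m3_net)
        iv = wave_interval(w_y, w_n)
        assert round(iv.lo, 2) == pytest.approx(0.13)
        assert iv.hi == pytest.approx(0.26 + math.sqrt(0.026 * 0.165)
                                      + math.sqrt(0.026 * 0.069)
                                      + math.sqrt(0.165 * 0.069), abs=1e-6)
        mirrored = wave_interval(w_n, w_y)
        assert mirrored.lo == pytest.approx(1 - iv.hi, abs=1e-12)
        assert mirrored.hi == pytest.approx(1 - iv.lo, abs=1e-12)

    def test_zero_interference_point_interval(self):
        net = make_two_node(0.3, 0.3, prior=1.0)
        w_y, w_n = waves_for(net)
        iv = wave_interval(w_y, w_n)
        assert iv.lo == pytest.approx(iv.hi, abs=1e-12)
        assert iv.lo == pytest.approx(0.3, abs=1e-12)

    def test_overlap_predicate(self):
        net = make_two_node(0.16, 0.03)  # PD (a) cooperate rates
        w_y, w_n = waves_for(net)
        assert not intervals_overlap(wave_interval(w_y, w_n), wave_interval(w_n, w_y))
        net = make_two_node(0.69, 0.58)  # 2SG (i)
        w_y, w_n = waves_for(net)
        i_y, i_n = wave_interval(w_y, w_n), wave_interval(w_n, w_y)
        assert i_n.lo == pytest.approx(0.0042, abs=5e-5)
        assert i_n.hi == pytest.approx(0.7258, abs=5e-5)
        assert intervals_overlap(i_y, i_n)
        assert intervals_overlap(WaveInterval(0, 0.5), WaveInterval(0.5, 1))

    def test_closed_form_equals_grid_search(self):
        """M = 2: closed form vs dense grid over the free wave's phase."""
        for p1, p2 in [(0.16, 0.03), (0.69, 0.58), (0.45, 0.63), (0.23, 0.18)]:
            net = make_two_node(p1, p2)
            w_y, w_n = waves_for(net)
            small = w_y if w_y.base <= w_n.base else w_n
            iv = wave_interval(small, w_n if small is w_y else w_y)
            grid = np.linspace(0, 2 * math.pi, 4096, endpoint=False)
            vals = [evaluate_wave(small, (d, 0.0)) for d in grid]
            assert iv.lo == pytest.approx(min(vals), abs=1e-6)
            assert iv.hi == pytest.approx(max(vals), abs=1e-6)

    def test_numeric_optimum_equals_coarse_grid(self, m3_net):
        """M = 3: optimiser vs an independent 128^2 grid over gauge-fixed phases."""
        w_y, w_n = waves_for(m3_net)
        iv = wave_interval(w_y, w_n)
        grid = np.linspace(0, 2 * math.pi, 128, endpoint=False)
        vals = [
            evaluate_wave(w_y, (a, b, 0.0)) for a, b in itertools.product(grid, grid)
        ]
        assert iv.lo == pytest.approx(min(vals), abs=1e-3)
        assert iv.hi == pytest.approx(max(vals), abs=1e-3)


class TestPrinciples:
    def test_entropy_pd_row_a(self):
        net = make_two_node(0.16, 0.03)
        w_y, w_n = waves_for(net)
        pred = entropy_principle(w_y, w_n)
        assert pred.principle == "entropy"
        assert round(pred.pq["not_y"] + 1e-12, 2) == pytest.approx(0.84)
        assert pred.pq["y"] + pred.pq["not_y"] == pytest.approx(1.0, abs=1e-12)

    def test_entropy_pd_row_d(self):
        net = make_two_node(0.07, 0.03)
        pred = entropy_principle(*waves_for(net))
        assert round(pred.pq["not_y"] + 1e-12, 2) == pytest.approx(0.90)

    def test_entropy_rejects_overlap(self):
        net = make_two_node(0.69, 0.58)
        with pytest.raises(PrincipleDispatchError):
            entropy_principle(*waves_for(net))

    @pytest.mark.parametrize(
        "p1, p2, expected",
        [(0.69, 0.58, 0.36), (0.72, 0.47, 0.39), (0.63, 0.45, 0.45)],
    )
    def test_mirror_two_stage_rows(self, p1, p2, expected):
        net = make_two_node(p1, p2)
        pred = mirror_principle(*waves_for(net))
        assert pred.principle == "mirror"
        assert round(pred.pq["y"] + 1e-12, 2) == pytest.approx(expected)

    def test_mirror_rejects_disjoint(self):
        net = make_two_node(0.16, 0.03)
        with pytest.raises(PrincipleDispatchError):
            mirror_principle(*waves_for(net))

    def test_equal_bases_use_mirror_amplitude(self):
        # p(y) = p(not_y) = 0.5: prediction is the counterpart amplitude
        net = make_two_node(0.7, 0.3)
        pred = predict_max_uncertainty(net, "Y")
        expected = 2 * math.sqrt(0.5 * 0.3 * 0.5 * 0.7)
        assert pred.principle == "mirror"
        assert pred.pq["y"] == pytest.approx(expected, abs=1e-12)


class TestFullPipeline:
    @pytest.mark.parametrize(
        "p_not_1, p_not_2, expected_not_y",
        [(0.84, 0.97, 0.84), (0.77, 0.82, 0.59), (0.93, 0.97, 0.90)],
    )
    def test_pd_predictions(self, p_not_1, p_not_2, expected_not_y):
        net = make_two_node(1 - p_not_1, 1 - p_not_2)
        pred = predict_max_uncertainty(net, "Y")
        assert pred.principle == "entropy"
        assert round(pred.pq["not_y"] + 1e-12, 2) == pytest.approx(expected_not_y)

    def test_2sg_row_iii(self):
        net = make_two_node(0.63, 0.45)
        pred = predict_max_uncertainty(net, "Y")
        assert pred.principle == "mirror"
        assert round(pred.pq["y"] + 1e-12, 2) == pytest.approx(0.45)

    def test_deterministic_tables_give_classical(self):
        net = make_two_node(1.0, 1.0)
        pred = predict_max_uncertainty(net, "Y")
        # p(y) = 1 exactly: no uncertainty, prediction collapses
        assert pred.pq["y"] == pytest.approx(1.0, abs=1e-12)
        assert pred.intervals["y"].width == pytest.approx(0.0, abs=1e-12)

    def test_relabel_invariance(self):
        """Swapping the query's two states swaps the pq values."""
        from qlbn import BayesNet, ConditionalTable, VariableSpec

        def build(states, dists):
            return BayesNet(
                [VariableSpec("X", ("x", "not_x")), VariableSpec("Y", states)],
                [
                    ConditionalTable("X", (), {(): (0.5, 0.5)}),
                    ConditionalTable("Y", ("X",), dists),
                ],
            )

        a = build(("y", "not_y"), {("x",): (0.16, 0.84), ("not_x",): (0.03, 0.97)})
        b = build(("not_y", "y"), {("x",): (0.84, 0.16), ("not_x",): (0.97, 0.03)})
        pa = predict_max_uncertainty(a, "Y")
        pb = predict_max_uncertainty(b, "Y")
        assert pa.pq["y"] == pytest.approx(pb.pq["y"], abs=1e-12)
        assert pa.pq["not_y"] == pytest.approx(pb.pq["not_y"], abs=1e-12)
        assert pa.principle == pb.principle

    def test_monotone_interference_shrinks_interval(self):
        """Pulling the conditionals together narrows nothing below zero and
        shrinks the gap between AM and GM, hence the attainable width."""
        widths = []
        for eps in (0.3, 0.2, 0.1, 0.0):
            net = make_two_node(0.4 - eps, 0.4 + eps)
            w_y, w_n = waves_for(net)
            iv = wave_interval(w_y, w_n)
            widths.append(iv.width)
            assert iv.width >= -1e-12
        assert widths == sorted(widths)

    def test_m2_complementarity_exact(self):
        for p1, p2 in [(0.16, 0.03), (0.69, 0.58), (0.45, 0.63)]:
            pred = predict_max_uncertainty(make_two_node(p1, p2), "Y")
            assert pred.pq["y"] + pred.pq["not_y"] == pytest.approx(1.0, abs=1e-12)

    def test_m3_entropy_dispatch(self, m3_net):
        pred = predict_max_uncertainty(m3_net, "Y")
        assert pred.principle == "entropy"
        assert round(pred.intervals["y"].lo, 2) == pytest.approx(0.13)
        assert pred.pq["y"] == pytest.approx(0.4746, abs=5e-5)
        # the M >= 3 endpoints need not be exact complements; defect recorded
        assert abs(pred.complementarity_defect) < 0.01
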