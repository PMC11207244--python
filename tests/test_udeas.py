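"""uDEAS optimizer: decoding, BSS/UDS mechanics, sensitivity, global search."""

import numpy as np
import pytest

from poseangle.udeas import (
    BinaryMatrix,
    OptimizerConfig,
    bisectional_search,
    decode,
    decode_row,
    encode_value,
    optimize,
    run_session,
    sensitivity,
    unidirectional_search,
)


class TestDecode:
    def test_midpoint_rule(self):
        assert decode("1", 0, 1) == 0.75
        assert decode("0", 0, 1) == 0.25
        assert decode("10", 0, 1) == 0.625  # refines "1"'s lower half

    def test_strictly_increasing_in_integer_value(self):
        for length in range(1, 9):
            vals = [decode_row(v, length, -2.0, 3.0) for v in range(1 << length)]
            assert all(a < b for a, b in zip(vals, vals[1:]))
            assert all(-2.0 < v < 3.0 for v in vals)

    def test_rejects_bad_rows(self):
        with pytest.raises(ValueError):
            decode("", 0, 1)
        with pytest.raises(ValueError):
            decode("012", 0, 1)

    def test_encode_inverts_decode(self):
        for length in (3, 6, 10):
            for v in (0, 5, (1 << length) - 1):
                if v >= (1 << length):
                    continue
                x = decode_row(v, length, -1, 4)
                assert encode_value(x, length, -1, 4) == v


class TestBssUds:
    def test_bss_keeps_better_child(self):
        # f(x) = (x - 0.9)^2 from row "1" on [0,1]: children decode to
        # 0.625 and 0.875; the "1" child (0.875) is closer to 0.9.
        m = BinaryMatrix([1], [1], [(0.0, 1.0)])
        f = lambda x: (x[0] - 0.9) ** 2
        (c0, c1), (x0, x1), direction = bisectional_search(m, 0, f)
        assert (x0, x1) == (0.625, 0.875)
        assert direction == +1
        assert m.rows() == ["11"]

    def test_bss_tie_keeps_zero_child(self):
        m = BinaryMatrix([1], [1], [(0.0, 1.0)])
        (c0, c1), _, direction = bisectional_search(m, 0, lambda x: 1.0)
        assert c0 == c1 == 1.0
        assert direction == -1
        assert m.rows() == ["10"]

    def test_bss_depth_exhausted_signal(self):
        m = BinaryMatrix([1], [3], [(0.0, 1.0)])
        assert bisectional_search(m, 0, lambda x: 0.0, max_depth=3) is None

    def test_uds_clamps_at_range_end(self):
        # from "11" on [0,1] moving +1: already at the top -> M = 0
        m = BinaryMatrix([3], [2], [(0.0, 1.0)])
        f = lambda x: (x[0] - 0.95) ** 2
        trace, _ = unidirectional_search(m, 0, +1, f, f(np.array([0.875])))
        assert trace == []
        assert m.values == [3]

    def test_uds_walks_monotone_function(self):
        # f decreasing in x, length 3 from "000": walks to "111", M = 7
        m = BinaryMatrix([0], [3], [(0.0, 1.0)])
        f = lambda x: -x[0]
        trace, best = unidirectional_search(m, 0, +1, f, f(m.decode_all()))
        assert len(trace) == 7
        assert m.values == [7]
        assert best == pytest.approx(-decode_row(7, 3, 0, 1))

    def test_uds_stops_at_first_worse_step(self):
        m = BinaryMatrix([2], [3], [(0.0, 1.0)])
        f = lambda x: (x[0] - decode_row(2, 3, 0, 1)) ** 2  # already optimal
        trace, _ = unidirectional_search(m, 0, +1, f, 0.0)
        assert trace == []
        assert m.values == [2]


class TestSensitivity:
    def test_hand_arithmetic(self):
        # BSS costs 4 and 1 at values 0.25 and 0.75, M = 0:
        # S = (|4-1| / 0.5) / 1 = 6
        s = sensitivity((4.0, 1.0), (0.25, 0.75), [], 0.75, 1.0)
        assert s == pytest.approx(6.0, abs=1e-9)

    def test_constant_cost_gives_zero(self):
        s = sensitivity((2.0, 2.0), (0.25, 0.75), [(0.875, 2.0)], 0.75, 2.0)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_uds_terms_divided_by_m_plus_one(self):
        # BSS slope 6 plus one UDS step of slope |1-0.5|/|0.875-0.75| = 4:
        # S = (6 + 4) / 2 = 5
        s = sensitivity((4.0, 1.0), (0.25, 0.75), [(0.875, 0.5)], 0.75, 1.0)
        assert s == pytest.approx(5.0, abs=1e-9)


class TestSession:
    def cfg(self, **kw):
        base = dict(initial_depth=2, max_depth=8, restarts=1, seed=0)
        base.update(kw)
        return OptimizerConfig(**base)

    def test_session_deepens_every_row_once(self):
        # canonical starting matrix 10;01;00 searched in order v1->v2->v3
        m = BinaryMatrix([2, 1, 0], [2, 2, 2], [(0, 1)] * 3)
        f = lambda x: float(np.sum((x - 0.3) ** 2))
        res = run_session(m, [0, 1, 2], f, self.cfg())
        assert m.lengths == [3, 3, 3]
        assert res.best_cost <= f(np.array([0.625, 0.375, 0.125]))

    def test_sensitivity_ranking_orders_next_session(self):
        # steepest variable should get the largest sensitivity score
        m = BinaryMatrix([2, 1, 0], [2, 2, 2], [(-1, 1)] * 3)
        f = lambda x: 100 * x[2] ** 2 + 10 * x[0] ** 2 + x[1] ** 2
        res = run_session(m, [0, 1, 2], f, self.cfg())
        s = res.sensitivities
        order = sorted(range(3), key=lambda i: (-s[i], i))
        assert order == [2, 0, 1]

    def test_single_variable_session(self):
        m = BinaryMatrix([1], [1], [(0, 1)])
        f = lambda x: (x[0] - 0.8) ** 2
        res = run_session(m, [0], f, self.cfg())
        assert res.best_cost <= f(np.array([0.75]))
        assert res.uds_counts.shape == (1,)


class TestOptimize:
    def test_1d_unimodal_within_grid_spacing_of_exhaustive_oracle(self):
        cfg = OptimizerConfig(initial_depth=2, max_depth=10, restarts=1, seed=3)
        for target in (0.3, 0.017, 0.876):
            f = lambda x, t=target: (x[0] - t) ** 2
            res = optimize(f, [(0.0, 1.0)], cfg)
            grid = np.array([decode_row(v, 10, 0, 1) for v in range(1 << 10)])
            oracle = grid[np.argmin((grid - target) ** 2)]
            spacing = 1.0 / (1 << 10)
            assert abs(res.x[0] - target) <= spacing
            assert abs(res.x[0] - oracle) <= spacing / 2 + 1e-15

    def test_3d_sphere(self):
        f = lambda x: float(np.sum(x ** 2))
        res = optimize(f, [(-1, 1)] * 3,
                       OptimizerConfig(max_depth=12, restarts=3, seed=2))
        assert res.cost <= 1e-4

    def test_best_cost_monotone_within_local_search(self):
        f = lambda x: float(np.sum((x - 0.2) ** 2))
        res = optimize(f, [(-1, 1)] * 4,
                       OptimizerConfig(max_depth=8, restarts=2, seed=9))
        for hist in res.history:
            assert all(a >= b - 1e-15 for a, b in zip(hist, hist[1:]))
        assert res.cost == min(res.restart_costs)

    def test_identical_seed_identical_trace(self):
        f = lambda x: float(np.sum(np.abs(x))) + 0.1 * float(np.sin(5 * x[0]))
        cfg = OptimizerConfig(max_depth=10, restarts=4, seed=17)
        r1 = optimize(f, [(-2, 2)] * 3, cfg)
        r2 = optimize(f, [(-2, 2)] * 3, cfg)
        assert np.array_equal(r1.x, r2.x)
        assert r1.cost == r2.cost
        assert r1.history == r2.history

    def test_rastrigin_beats_random_sampling_floor(self):
        def rastrigin(x):
            return float(10 * x.size + np.sum(x ** 2 - 10 * np.cos(2 * np.pi * x)))

        cfg = OptimizerConfig(max_depth=10, restarts=10, seed=5)
        res = optimize(rastrigin, [(-5.12, 5.12)] * 2, cfg)
        # a local search never worsens its own starting matrix
        rng = np.random.default_rng(5)
        floor = min(
            rastrigin(BinaryMatrix.random([(-5.12, 5.12)] * 2, 2, rng).decode_all())
            for _ in range(10)
        )
        assert res.cost <= floor

    def test_sequential_and_sensitivity_orderings_both_converge(self):
        f = lambda x: float((x[0] - 0.4) ** 2 + 5 * (x[1] + 0.3) ** 2)
        seq = optimize(f, [(-1, 1)] * 2, OptimizerConfig(
            max_depth=12, restarts=3, seed=4, ordering="sequential"))
        sen = optimize(f, [(-1, 1)] * 2, OptimizerConfig(
            max_depth=12, restarts=3, seed=4, ordering="sensitivity"))
        assert seq.cost <= 1e-5
        assert sen.cost <= 1e-5

    def test_invalid_config_and_bounds(self):
        with pytest.raises(ValueError):
            OptimizerConfig(initial_depth=0)
        with pytest.raises(ValueError):
            OptimizerConfig(restarts=0)
        with pytest.raises(ValueError):
            OptimizerConfig(ordering="random")
        with pytest.raises(ValueError):
            optimize(lambda x: 0.0, [(0.0, 0.0)])


def test_binary_matrix_validation():
    with pytest.raises(ValueError):
        BinaryMatrix([4], [2], [(0, 1)])   # value needs 3 bits
    with pytest.raises(ValueError):
        BinaryMatrix([0], [1], [(1.0, 0.0)])
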