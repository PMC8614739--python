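import numpy as np
import pytest

from ratemc.mc_propagation import (
    EvaluationNode,
    PropagationError,
    propagate_chain,
    relative_error,
    sample_gaussian,
)
from ratemc.data_model import MCEnsemble


def node(name, f, inputs):
    return EvaluationNode(name=name, function=lambda d: f(d), inputs=inputs)


class TestSampleGaussian:
    def test_zero_sigma_reproduces_input_exactly(self):
        rng = np.random.default_rng(0)
        out = sample_gaussian(np.array([1.0, 2.0]), 0.0, 100, rng)
        assert out.shape == (100, 2)
        assert np.all(out == [1.0, 2.0])

    def test_ensemble_mean_within_standard_error_bound(self):
        rng = np.random.default_rng(1)
        out = sample_gaussian(np.array([10.0]), 1.0, 500, rng)
        # 3 sigma / sqrt(N) ~ 0.134
        assert abs(out.mean() - 10.0) < 0.15

    def test_draws_are_independent_per_position(self):
        rng = np.random.default_rng(2)
        out = sample_gaussian(np.zeros(2), 1.0, 4000, rng)
        assert abs(np.corrcoef(out.T)[0, 1]) < 0.05


class TestPropagateChain:
    def test_identity_node_passes_sigma_through(self):
        res = propagate_chain(
            [node("id", lambda d: d["x"], ["x"])],
            {"x": (np.array([2.0]), np.array([0.3]))},
            n=500,
            seed=3,
        )
        assert res["id"].sigma[0] == pytest.approx(0.3, rel=0.10)

    def test_linear_node_scales_sigma(self):
        res = propagate_chain(
            [node("triple", lambda d: 3.0 * d["x"], ["x"])],
            {"x": (np.array([5.0]), np.array([1.0]))},
            n=500,
            seed=4,
        )
        # sigma estimator SE ~ sigma/sqrt(2(N-1)); allow 3 of those
        se = 3.0 / np.sqrt(2 * 499)
        assert abs(res["triple"].sigma[0] - 3.0) < 3 * se

    def test_square_node_matches_large_sample_oracle(self):
        res = propagate_chain(
            [node("sq", lambda d: d["x"] ** 2, ["x"])],
            {"x": (np.array([10.0]), np.array([1.0]))},
            n=500,
            seed=5,
        )
        oracle = np.std(
            (10.0 + np.random.default_rng(99).standard_normal(1_000_000)) ** 2, ddof=1
        )
        assert res["sq"].sigma[0] == pytest.approx(oracle, rel=0.05)
        # first-order analytic propagation gives 2*x*sigma = 20 as sanity bound
        assert res["sq"].sigma[0] == pytest.approx(20.0, rel=0.15)

    def test_zero_input_sigma_gives_exactly_deterministic_chain(self):
        nodes = [
            node("a", lambda d: 2.0 * d["x"] + 1.0, ["x"]),
            node("b", lambda d: d["a"] ** 2, ["a"]),
        ]
        res = propagate_chain(nodes, {"x": (np.array([3.0]), np.array([0.0]))}, n=50, seed=6)
        assert res["b"].sigma[0] == 0.0
        assert res["b"].mean[0] == pytest.approx(49.0)

    def test_fixed_seed_is_bit_reproducible(self):
        raw = {"x": (np.array([1.0, 2.0]), np.array([0.1, 0.2]))}
        nodes = [node("y", lambda d: d["x"] * 2, ["x"])]
        a = propagate_chain(nodes, raw, n=200, seed=7)
        b = propagate_chain(nodes, raw, n=200, seed=7)
        np.testing.assert_array_equal(a["y"].realizations, b["y"].realizations)

    def test_different_seeds_agree_within_sampling_tolerance(self):
        raw = {"x": (np.array([4.0]), np.array([0.5]))}
        nodes = [node("y", lambda d: d["x"] * 2, ["x"])]
        a = propagate_chain(nodes, raw, n=500, seed=8)
        b = propagate_chain(nodes, raw, n=500, seed=9)
        assert a["y"].sigma[0] == pytest.approx(b["y"].sigma[0], rel=0.2)

    def test_node_insertion_does_not_reshuffle_other_draws(self):
        raw = {"x": (np.array([1.0]), np.array([0.1]))}
        base = propagate_chain([node("y", lambda d: d["x"], ["x"])], raw, n=100, seed=10)
        extended = propagate_chain(
            [node("y", lambda d: d["x"], ["x"]), node("z", lambda d: -d["x"], ["x"])],
            raw,
            n=100,
            seed=10,
        )
        np.testing.assert_array_equal(
            base["y"].realizations, extended["y"].realizations
        )

    def test_chained_and_coupled_agree_for_near_linear_chain(self):
        raw = {"x": (np.array([5.0]), np.array([0.2]))}
        nodes = [
            node("a", lambda d: 2.0 * d["x"], ["x"]),
            node("b", lambda d: d["a"] + 1.0, ["a"]),
        ]
        chained = propagate_chain(nodes, raw, n=500, seed=11, mode="chained")
        coupled = propagate_chain(nodes, raw, n=500, seed=11, mode="coupled")
        assert chained["b"].sigma[0] == pytest.approx(coupled["b"].sigma[0], rel=0.15)

    def test_sporadic_failures_are_dropped(self):
        def sometimes(d):
            if d["x"][0] > 1.25:  # ~ 1% of draws at sigma 0.1
                raise RuntimeError("boom")
            return d["x"]

        res = propagate_chain(
            [EvaluationNode("f", lambda d: sometimes(d), ["x"])],
            {"x": (np.array([1.0]), np.array([0.1]))},
            n=500,
            seed=12,
        )
        assert 0 < res.failures["f"] <= 25

    def test_too_many_failures_abort_with_node_name(self):
        def mostly_fails(d):
            if d["x"][0] > 1.0:
                raise RuntimeError("boom")
            return d["x"]

        with pytest.raises(PropagationError, match="'f'"):
            propagate_chain(
                [EvaluationNode("f", lambda d: mostly_fails(d), ["x"])],
                {"x": (np.array([1.0]), np.array([0.1]))},
                n=200,
                seed=13,
            )

    def test_cycle_detection(self):
        nodes = [
            EvaluationNode("a", lambda d: d["b"], ["b"]),
            EvaluationNode("b", lambda d: d["a"], ["a"]),
        ]
        with pytest.raises(PropagationError, match="cycle"):
            propagate_chain(nodes, {}, n=10, seed=0)

    def test_unresolved_input_detected(self):
        with pytest.raises(PropagationError, match="resolves to nothing"):
            propagate_chain(
                [EvaluationNode("a", lambda d: d["ghost"], ["ghost"])], {}, n=10, seed=0
            )


class TestRelativeError:
    def test_constant_series(self):
        ens = MCEnsemble(realizations=np.array([[1.8, 1.8], [2.2, 2.2]]), n=2)
        # mean 2, sigma ~0.28: ratio equal at both positions
        assert relative_error(ens) == pytest.approx(ens.sigma[0] / 2.0)

    def test_zero_crossing_positions_are_masked(self):
        r = np.array([[1.0, 0.001, 2.0], [3.0, -0.001, 2.2]])
        ens = MCEnsemble(realizations=r, n=2)
        val = relative_error(ens, mask_epsilon=0.01)
        assert np.isfinite(val)

    def test_all_masked_raises(self):
        ens = MCEnsemble(realizations=np.zeros((3, 2)), n=3)
        with pytest.raises(ValueError, match="masked"):
            relative_error(ens, mask_epsilon=1.0)
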