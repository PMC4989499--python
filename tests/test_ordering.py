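import itertools
import math

import numpy as np
import pytest

from wavecrest import (
    CellOrder,
    aggregated_mse,
    count_admissible_orders,
    eni_order,
    exhaustive_oracle,
    recover_order,
    two_opt_refine,
)

from conftest import make_rescaled


def _random_instance(rng, block_sizes=(4, 4), n_genes=3):
    labels = []
    for b, size in enumerate(block_sizes):
        labels += [f"T{b}"] * size
    vals = rng.normal(size=(n_genes, len(labels)))
    return make_rescaled(vals, labels)


def _normal_equations_mse(y, degree):
    """Literal normal-equations least squares, independent of the package path."""
    n = len(y)
    x = np.linspace(0.0, 1.0, n)
    X = np.column_stack([x**k for k in range(degree + 1)])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    resid = y - X @ beta
    return float(resid @ resid / n)


class TestAggregatedMSE:
    def test_exact_cubic_gives_zero(self):
        x = np.linspace(0, 1, 12)
        y = 2 - 3 * x + 0.5 * x**2 + 4 * x**3
        data = make_rescaled(y[None, :], ["A"] * 6 + ["B"] * 6)
        order = CellOrder.from_data(data, np.arange(12))
        assert aggregated_mse(order, data, ["g0"], degree=3) == pytest.approx(0, abs=1e-12)

    def test_sums_over_genes(self, rng):
        data = _random_instance(rng, (5, 5), n_genes=2)
        order = CellOrder.from_data(data, np.arange(10))
        total = aggregated_mse(order, data, ["g0", "g1"], degree=2)
        per_gene = [
            aggregated_mse(order, data, [g], degree=2) for g in ("g0", "g1")
        ]
        assert total == pytest.approx(sum(per_gene), rel=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        data = _random_instance(rng, (15, 15), n_genes=5)
        order = CellOrder.from_data(data, np.arange(30))
        for degree in (1, 2, 3):
            total = aggregated_mse(order, data, list(data.gene_ids), degree)
            expected = sum(
                _normal_equations_mse(data.values.loc[g].to_numpy(), degree)
                for g in data.gene_ids
            )
            assert total == pytest.approx(expected, abs=1e-9)

    def test_rejects_missing_gene_and_short_order(self, rng):
        data = _random_instance(rng, (2, 2))
        order = CellOrder.from_data(data, np.arange(4))
        with pytest.raises(KeyError):
            aggregated_mse(order, data, ["nope"], 2)
        with pytest.raises(ValueError):
            aggregated_mse(order, data, ["g0"], degree=3)


class TestCellOrder:
    def test_rejects_mixed_time_blocks(self, rng):
        data = _random_instance(rng, (2, 2))
        with pytest.raises(ValueError, match="mixed"):
            CellOrder.from_data(data, [0, 2, 1, 3])

    def test_rejects_non_permutation(self, rng):
        data = _random_instance(rng, (2, 2))
        with pytest.raises(ValueError, match="permutation"):
            CellOrder(np.array([0, 0, 1, 2]), [(0, 2), (2, 4)], ["T0", "T1"])


class TestENI:
    def test_recovers_monotone_order_up_to_reversal(self, rng):
        # single marker strictly monotone along the latent order, 2x3 cells
        latent = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        y = 2.0 * latent - 1.0
        shuffle = np.array([2, 0, 1, 5, 3, 4])  # scramble within blocks
        data = make_rescaled(y[shuffle][None, :], ["A"] * 3 + ["B"] * 3)
        oracle_order, oracle_mse = exhaustive_oracle(data, ["g0"], degree=2)
        best = recover_order(data, ["g0"], degree=2, seed=0, n_restarts=3, n_iter=2000)
        assert aggregated_mse(best, data, ["g0"], 2) == pytest.approx(
            oracle_mse, abs=1e-9
        )
        # recovered order sorts the marker monotonically within blocks
        vals = data.values.to_numpy()[0][best.order]
        diffs = np.diff(vals)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_identical_cells_still_valid_and_deterministic(self):
        data = make_rescaled(np.zeros((2, 8)), ["A"] * 4 + ["B"] * 4)
        o1 = eni_order(data, ["g0", "g1"], degree=2, seed=7)
        o2 = eni_order(data, ["g0", "g1"], degree=2, seed=7)
        np.testing.assert_array_equal(o1.order, o2.order)
        CellOrder.from_data(data, o1.order)  # validates the block constraint

    def test_time_blocks_never_mix(self, rng):
        for seed in range(5):
            data = _random_instance(rng, (3, 4, 2), n_genes=2)
            o = eni_order(data, ["g0", "g1"], degree=2, seed=seed)
            codes = data.time.cat.codes.to_numpy()[o.order]
            assert (np.diff(codes) >= 0).all()

    def test_requires_two_time_points(self, rng):
        data = _random_instance(rng, (6,))
        with pytest.raises(ValueError):
            eni_order(data, ["g0"], degree=2, seed=0)


class TestTwoOpt:
    def test_noop_at_optimum(self, rng):
        data = _random_instance(rng, (3, 3), n_genes=2)
        opt, _ = exhaustive_oracle(data, ["g0", "g1"], degree=2)
        refined = two_opt_refine(opt, data, ["g0", "g1"], degree=2, n_iter=3000, seed=0)
        assert aggregated_mse(refined, data, ["g0", "g1"], 2) == pytest.approx(
            aggregated_mse(opt, data, ["g0", "g1"], 2), abs=1e-12
        )

    def test_improves_scrambled_monotone_instance(self):
        latent = np.linspace(0, 1, 12)
        y = latent * 2 - 1
        scramble = np.concatenate(
            [np.array([3, 0, 5, 1, 4, 2]), 6 + np.array([4, 1, 5, 0, 2, 3])]
        )
        data = make_rescaled(y[scramble][None, :], ["A"] * 6 + ["B"] * 6)
        start = CellOrder.from_data(data, np.arange(12))
        before = aggregated_mse(start, data, ["g0"], 2)
        refined = two_opt_refine(start, data, ["g0"], degree=2, n_iter=5000, seed=1)
        assert aggregated_mse(refined, data, ["g0"], 2) < before

    def test_mse_trace_non_increasing(self, rng):
        data = _random_instance(rng, (5, 5), n_genes=3)
        start = CellOrder.from_data(data, np.arange(10))
        _, trace = two_opt_refine(
            start, data, list(data.gene_ids), degree=2, n_iter=2000, seed=3,
            return_trace=True,
        )
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_zero_iterations_returns_input(self, rng):
        data = _random_instance(rng, (3, 3))
        start = CellOrder.from_data(data, np.arange(6))
        out = two_opt_refine(start, data, ["g0"], degree=2, n_iter=0, seed=0)
        np.testing.assert_array_equal(out.order, start.order)


class TestExhaustiveOracle:
    def test_enumeration_count(self, rng):
        data = _random_instance(rng, (2, 2))
        assert count_admissible_orders(data) == math.factorial(2) * math.factorial(2)
        # explicit check against itertools enumeration
        blocks = [data.cells_at("T0"), data.cells_at("T1")]
        n_orders = sum(
            1
            for _ in itertools.product(
                *(itertools.permutations(b.tolist()) for b in blocks)
            )
        )
        assert n_orders == 4

    def test_oracle_lower_bounds_heuristic(self, rng):
        for seed in range(5):
            data = _random_instance(rng, (3, 3), n_genes=2)
            _, oracle_mse = exhaustive_oracle(data, ["g0", "g1"], degree=2)
            heur = recover_order(
                data, ["g0", "g1"], degree=2, seed=seed, n_restarts=2, n_iter=1000
            )
            assert oracle_mse <= aggregated_mse(heur, data, ["g0", "g1"], 2) + 1e-12

    def test_noiseless_monotone_reaches_zero(self):
        latent = np.linspace(0, 1, 8)
        y = 3 * latent - 1.5
        data = make_rescaled(y[None, :], ["A"] * 4 + ["B"] * 4)
        _, mse = exhaustive_oracle(data, ["g0"], degree=2)
        assert mse == pytest.approx(0.0, abs=1e-12)

    def test_refuses_large_instances(self, rng):
        data = _random_instance(rng, (6, 6, 6))
        with pytest.raises(ValueError, match="max_orders"):
            exhaustive_oracle(data, ["g0"], degree=2)


class TestDeterminism:
    def test_identical_seed_identical_order(self, rng):
        data = _random_instance(rng, (6, 6), n_genes=3)
        runs = [
            recover_order(data, list(data.gene_ids), degree=2, seed=42, n_iter=2000)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].order, runs[1].order)
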