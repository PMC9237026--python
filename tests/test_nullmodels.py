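import itertools

import numpy as np
import pytest

from trophicstab import (
    FoodWeb,
    Link,
    Node,
    curveball,
    null_distribution,
    randomize_web,
    shuffle_weights,
    to_diet_matrix,
)


class TestCurveball:
    def test_checkerboard_stays_in_two_state_space(self):
        a = np.eye(2, dtype=int)
        seen = set()
        for seed in range(20):
            out = curveball(a, 10, seed=seed)
            assert (out.sum(0) == 1).all() and (out.sum(1) == 1).all()
            seen.add(out.tobytes())
        # only two matrices share these marginals — and both get visited
        assert len(seen) == 2

    def test_all_ones_invariant(self):
        a = np.ones((3, 4), dtype=int)
        assert (curveball(a, 50, seed=1) == a).all()

    def test_marginals_preserved_on_every_draw(self, scenario_pair, rng):
        a = to_diet_matrix(scenario_pair[0]).binary()
        for seed in range(20):
            out = curveball(a, 5 * a.shape[0], seed=seed)
            assert (out.sum(0) == a.sum(0)).all()
            assert (out.sum(1) == a.sum(1)).all()

    def test_negative_trades_rejected(self):
        with pytest.raises(ValueError):
            curveball(np.eye(2, dtype=int), -1)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            curveball(np.array([[0.5, 0], [0, 1]]), 3)


class TestShuffleWeights:
    def test_single_prey_column_unchanged(self, chain3):
        q = to_diet_matrix(chain3)
        out = shuffle_weights(q, seed=3)
        np.testing.assert_array_equal(out.values, q.values)

    def test_two_weight_column_is_a_permutation(self, diamond):
        q = to_diet_matrix(diamond)
        q.values[1, 0], q.values[2, 0] = 0.6, 0.4  # A's column
        outs = {tuple(shuffle_weights(q, seed=s).values[:, 0]) for s in range(20)}
        assert outs == {(0.0, 0.6, 0.4), (0.0, 0.4, 0.6)}

    def test_column_sums_exactly_preserved(self, scenario_pair):
        q = to_diet_matrix(scenario_pair[1])
        out = shuffle_weights(q, seed=11)
        np.testing.assert_allclose(
            out.values.sum(0), q.values.sum(0), atol=1e-12
        )

    def test_multiset_of_weights_kept_per_predator(self, scenario_pair):
        q = to_diet_matrix(scenario_pair[0])
        out = shuffle_weights(q, seed=4)
        for j in range(q.n):
            assert sorted(q.values[:, j][q.values[:, j] > 0]) == pytest.approx(
                sorted(out.values[:, j][out.values[:, j] > 0])
            )


class TestRandomizeWeb:
    def test_degrees_preserved(self, scenario_pair):
        web = scenario_pair[0]
        q = to_diet_matrix(web)
        for seed in range(5):
            null = randomize_web(web, weighted=True, seed=seed)
            qn = to_diet_matrix(null)
            assert (qn.binary().sum(0) == q.binary().sum(0)).all()
            assert (qn.binary().sum(1) == q.binary().sum(1)).all()

    def test_weighted_keeps_diet_multisets(self, scenario_pair):
        web = scenario_pair[0]
        q = to_diet_matrix(web)
        null = randomize_web(web, weighted=True, seed=2)
        qn = to_diet_matrix(null)
        for j in range(q.n):
            assert sorted(qn.values[:, j][qn.values[:, j] > 0]) == pytest.approx(
                sorted(q.values[:, j][q.values[:, j] > 0])
            )


class TestNullDistribution:
    def test_mtl_values_bounded_below(self, chain3):
        ens = null_distribution(chain3, "mTL", n=5, seed=1)
        assert len(ens.values) == 5
        assert (ens.values >= 1.0).all()

    def test_invariant_web_gives_constant_ensemble(self):
        # nested prey sets admit no curveball trade: the web is a fixed point
        web = FoodWeb(
            [Node(i) for i in "ABC"],
            [Link("B", "A"), Link("C", "A", 0.5), Link("C", "B", 0.5)],
        )
        from trophicstab import mean_trophic_level, trophic_levels

        empirical = mean_trophic_level(trophic_levels(web, weighted=False))
        ens = null_distribution(web, "mTL", n=8, seed=0)
        np.testing.assert_allclose(ens.values, empirical)

    def test_reproducible_bit_for_bit(self, scenario_pair):
        web = scenario_pair[0]
        e1 = null_distribution(web, "omnivory", n=6, seed=9, weighted=True)
        e2 = null_distribution(web, "omnivory", n=6, seed=9, weighted=True)
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_unknown_metric_rejected(self, chain3):
        with pytest.raises(ValueError, match="unknown metric"):
            null_distribution(chain3, "pagerank", n=2)

    def test_recipe_recorded(self, chain3):
        ens = null_distribution(chain3, "mTL", n=3, seed=5, trades_per_node=7)
        assert ens.recipe == {
            "n": 3, "seed": 5, "trades_per_node": 7,
            "weighted": False, "epsilon": 1.0,
        }


def enumerate_fixed_marginal_matrices(row_sums, col_sums):
    """All 0/1 matrices with the given marginals, by brute force over rows."""
    n_rows, n_cols = len(row_sums), len(col_sums)
    options = [
        [c for c in itertools.combinations(range(n_cols), k)] for k in row_sums
    ]
    out = []
    for combo in itertools.product(*options):
        m = np.zeros((n_rows, n_cols), dtype=np.int8)
        for i, cols in enumerate(combo):
            m[i, list(cols)] = 1
        if (m.sum(0) == np.asarray(col_sums)).all():
            out.append(m)
    return out


def test_curveball_samples_fixed_marginal_matrices_uniformly():
    """Empirical distribution over a fully enumerable 4x4 case matches the
    uniform distribution on the fixed-marginal ensemble (chi-squared GOF)."""
    import scipy.stats

    start = np.array(
        [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]], dtype=int
    )
    universe = enumerate_fixed_marginal_matrices([2, 2, 2, 2], [2, 2, 2, 2])
    index = {m.tobytes(): i for i, m in enumerate(universe)}
    counts = np.zeros(len(universe))
    rng = np.random.default_rng(2024)
    n_runs = 9000
    for _ in range(n_runs):
        out = curveball(start, 30, seed=rng)
        counts[index[out.tobytes()]] += 1
    assert counts.sum() == n_runs
    _, p = scipy.stats.chisquare(counts)
    assert p > 0.01
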