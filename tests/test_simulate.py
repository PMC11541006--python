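"""Population simulation: birth rates, stopping, determinism, neutrality,
lineage trees and summary statistics."""

import numpy as np
import pytest
from scipy import stats

from ecdna.segregation import CosegParams
from ecdna.simulate import (SimulationParams, StopCondition, compute_birth_rate,
                            simulate_leaf_copies, simulate_population,
                            subpopulation_fractions, summarize_population)


def neutral_params(target, seed, k=(5, 5), gamma=0.0):
    return SimulationParams(k_init=k, coseg=CosegParams(gamma=gamma),
                            stop=StopCondition(target_cells=target), seed=seed)


class TestBirthRate:
    def test_base_rate_without_ecdna(self):
        p = SimulationParams(stop=StopCondition(target_cells=10))
        assert compute_birth_rate((0, 0), p) == pytest.approx(0.5)

    def test_single_species_selection(self):
        p = SimulationParams(s_plus_minus=0.2, stop=StopCondition(target_cells=10))
        assert compute_birth_rate((3, 0), p) == pytest.approx(0.6)

    def test_coselection_doubles_rate(self):
        p = SimulationParams(s_plus_plus=1.0, stop=StopCondition(target_cells=10))
        assert compute_birth_rate((1, 1), p) == pytest.approx(1.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(s_plus_plus=-1.0, stop=StopCondition(target_cells=10))

    def test_waiting_time_draws(self, rng):
        from ecdna.simulate import draw_division_event

        p = SimulationParams(death_rate=0.4, s_plus_plus=1.0,
                             stop=StopCondition(target_cells=10))
        evs = [draw_division_event((2, 3), p, rng) for _ in range(4000)]
        assert all(ev.lambda1 == 1.0 for ev in evs)
        mean_tb = np.mean([ev.t_birth for ev in evs])
        assert mean_tb == pytest.approx(1.0, rel=0.1)
        # P(divide) = lambda / (lambda + mu)
        frac = np.mean([ev.divides for ev in evs])
        assert frac == pytest.approx(1.0 / 1.4, abs=0.03)


def test_stop_at_one_cell_returns_founder():
    res = simulate_population(neutral_params(1, seed=7, k=(3, 9)))
    assert res.n_cells == 1
    assert tuple(res.leaf_copies[0]) == (3, 9)
    assert res.tree.n_leaves == 1


def test_stop_condition_requires_a_bound():
    with pytest.raises(ValueError):
        StopCondition()


def test_determinism_and_record_invariance():
    p = neutral_params(500, seed=11, gamma=0.8)
    a = simulate_population(p, keep_tree=False)
    b = simulate_population(p, keep_tree=False)
    c = simulate_population(p, keep_tree=True)
    np.testing.assert_array_equal(a.leaf_copies, b.leaf_copies)
    np.testing.assert_array_equal(a.leaf_copies, c.leaf_copies)
    d = simulate_population(neutral_params(500, seed=12, gamma=0.8), keep_tree=False)
    assert not np.array_equal(a.leaf_copies, d.leaf_copies)


def test_neutral_mean_copy_number_is_conserved():
    """Binomial segregation after doubling is a martingale: the expected
    leaf copy number equals k_init under neutrality."""
    means = []
    for rep in range(50):
        leaves, _ = simulate_leaf_copies(neutral_params(1000, seed=100 + rep))
        means.append(leaves.mean(axis=0))
    means = np.array(means)
    for j in (0, 1):
        se = means[:, j].std(ddof=1) / np.sqrt(means.shape[0])
        assert abs(means[:, j].mean() - 5.0) < 3 * se


def test_supercritical_growth_reaches_target():
    for seed in range(5):
        res = simulate_population(neutral_params(2000, seed=seed), keep_tree=False)
        assert not res.extinct and res.n_cells == 2000


def test_extinction_is_a_result_not_an_error():
    p = SimulationParams(death_rate=5.0, k_init=(5, 5),
                         stop=StopCondition(target_cells=100_000), seed=3)
    res = simulate_population(p, keep_tree=False)
    assert res.extinct
    assert res.n_cells == 0


def test_time_stop_counts_cells_midwait():
    p = SimulationParams(stop=StopCondition(target_time=4.0), seed=5)
    res = simulate_population(p, keep_tree=False, max_cells=100_000)
    assert res.final_time == pytest.approx(4.0)
    assert res.n_cells >= 1


def test_tree_matches_leaves_and_exports_newick():
    res = simulate_population(neutral_params(200, seed=21, gamma=1.0))
    tree = res.tree
    assert tree.n_leaves == 200
    states = np.array([tree.leaf_states[i] for i in tree.leaf_ids])
    np.testing.assert_array_equal(np.sort(states, axis=0),
                                  np.sort(res.leaf_copies, axis=0))
    nwk = tree.to_newick()
    import dendropy

    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert len(parsed.leaf_nodes()) == 200


def test_tree_with_death_excludes_dead_lineages():
    p = SimulationParams(death_rate=0.2, s_plus_plus=1.0, k_init=(5, 5),
                         stop=StopCondition(target_cells=150), seed=9)
    res = simulate_population(p, keep_tree=True)
    if res.extinct:
        pytest.skip("population went extinct at this seed")
    nwk = res.tree.to_newick(include_dead=False)
    import dendropy

    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert len(parsed.leaf_nodes()) == res.n_cells


class TestSummaries:
    def test_co_occurrence_indicator(self):
        s = summarize_population(np.array([[2, 3], [0, 5], [1, 1]]), m=1)
        assert s.co_occurrence == pytest.approx(1 / 3)

    def test_perfect_linear_dependence(self):
        leaves = np.array([[1, 2], [2, 4], [3, 6], [5, 10]])
        s = summarize_population(leaves, m=0, transform="raw")
        assert s.correlation == pytest.approx(1.0)

    def test_constant_species_flags_undefined(self):
        s = summarize_population(np.array([[4, 4], [4, 4]]), m=1)
        assert not s.correlation_defined
        assert np.isnan(s.correlation)
        assert s.co_occurrence == 1.0

    def test_log_transform(self):
        leaves = np.array([[1, 10], [3, 2], [7, 30], [0, 1]])
        s = summarize_population(leaves, m=1, transform="log")
        expect = np.corrcoef(np.log1p(leaves[:, 0]), np.log1p(leaves[:, 1]))[0, 1]
        assert s.correlation == pytest.approx(expect)

    def test_empty_leaves_rejected(self):
        with pytest.raises(ValueError):
            summarize_population(np.zeros((0, 2)))

    def test_fraction_partition(self):
        pure, mix, free = subpopulation_fractions(
            np.array([[1, 1], [2, 0], [0, 0], [0, 3]]))
        assert (pure, mix, free) == (0.5, 0.25, 0.25)
        assert subpopulation_fractions(np.array([[0, 0]] * 4)) == (0, 0, 1)
        assert subpopulation_fractions(np.array([[2, 1]] * 4)) == (0, 1, 0)

    def test_fractions_sum_to_one(self, rng):
        leaves = rng.integers(0, 4, size=(200, 2))
        pure, mix, free = subpopulation_fractions(leaves)
        assert pure + mix + free == pytest.approx(1.0, abs=1e-12)


def test_cell_level_model_reproduces_orderings():
    """The cell-level (half-pairing Gillespie) variant shows the same two
    qualitative orderings as the element-level rule: correlation driven by
    co-segregation, co-occurrence by co-selection."""
    def batch(gamma, s_pp, n_rep=50):
        cs, rs = [], []
        for rep in range(n_rep):
            p = SimulationParams(
                k_init=(5, 5), s_minus_plus=0.2, s_plus_minus=0.2,
                s_plus_plus=s_pp, coseg=CosegParams(gamma=gamma, model="cell_level"),
                stop=StopCondition(target_cells=10_000), seed=3000 + rep)
            leaves, _ = simulate_leaf_copies(p)
            s = summarize_population(leaves, m=1)
            cs.append(s.co_occurrence)
            rs.append(s.correlation if s.correlation_defined else 0.0)
        return np.array(cs), np.array(rs)

    # gamma: 1.0 couples the high halves, 0.5 is the independent baseline
    _, r_hi = batch(1.0, 1.0)
    c_hi, r_lo = batch(0.5, 1.0)
    c_lo, _ = batch(0.5, 0.0)
    assert stats.ttest_ind(r_hi, r_lo).pvalue < 0.05 and r_hi.mean() > r_lo.mean()
    assert stats.ttest_ind(c_hi, c_lo).pvalue < 0.05 and c_hi.mean() > c_lo.mean()
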