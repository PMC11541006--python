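"""Division-level segregation rules: exact identities, conservation, and
distributional reductions to independent binomial splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecdna.segregation import (CopyState, CosegParams, element_coupled_parts,
                               sample_divisions, segregate)


def binomial_gof_pvalue(samples, n, p=0.5):
    """Chi-square goodness of fit of integer samples against Binomial(n, p),
    pooling tail bins to keep expected counts >= 5."""
    samples = np.asarray(samples)
    obs = np.bincount(samples, minlength=n + 1).astype(float)
    exp = stats.binom.pmf(np.arange(n + 1), n, p) * samples.shape[0]
    # pool adjacent bins until every expected count is >= 5
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    pooled_obs[-1] += acc_o
    pooled_exp[-1] += acc_e
    pooled_exp = np.array(pooled_exp) * (sum(pooled_obs) / sum(pooled_exp))
    return stats.chisquare(pooled_obs, pooled_exp).pvalue


def params_for(model, **kw):
    return CosegParams(model=model, **kw)


@pytest.mark.parametrize("model,kw", [
    ("element_level", {"gamma": 0.7}),
    ("cell_level", {"gamma": 0.9}),
    ("fraction_coupled", {"coupled_fraction": 0.5}),
])
def test_empty_parent_gives_empty_daughters(model, kw, rng):
    out = segregate(CopyState([0, 0]), params_for(model, **kw), rng)
    assert out.daughter1[0] == out.daughter1[1] == 0
    assert out.daughter2[0] == out.daughter2[1] == 0


def test_element_coupled_parts_fully_proportional():
    # parent (10, 10), gamma=1, anchor split 14/6: coupled parts are exactly
    # 14 and 6, nothing left for the random remainder
    c1, c2 = element_coupled_parts(10, 10, 1.0, 14)
    assert (c1, c2) == (14, 6)
    assert 2 * 10 - c1 - c2 == 0
    # absent anchor: no signal to couple to
    assert element_coupled_parts(0, 10, 1.0, 0) == (0, 0)


def test_element_coupled_parts_floor():
    # gamma=0.5, parent (10, 10), anchor split 13/7:
    # 0.5*20*13/20 = 6.5 -> 6 and 0.5*20*7/20 = 3.5 -> 3
    assert element_coupled_parts(10, 10, 0.5, 13) == (6, 3)


@pytest.mark.parametrize("model,kw,column", [
    ("element_level", {"gamma": 0.0}, 1),      # species 2 under gamma=0
    ("element_level", {"gamma": 0.7}, 0),      # anchor is always binomial
    ("cell_level", {"gamma": 0.5}, 0),
    ("cell_level", {"gamma": 0.5}, 1),
    ("fraction_coupled", {"coupled_fraction": 0.0}, 1),
])
def test_reduction_to_independent_binomial(model, kw, column, rng):
    """gamma=0 (element), gamma=0.5 (cell) and phi=0 (fraction-coupled) all
    reduce each species' marginal to Binomial(2N, 1/2)."""
    parent = CopyState([10, 10])
    d1, _ = sample_divisions(parent, params_for(model, **kw), 100_000, rng)
    assert binomial_gof_pvalue(d1[:, column], 20) > 0.01


def test_cell_level_half_gamma_uncorrelated(rng):
    parent = CopyState([10, 10])
    d1, _ = sample_divisions(parent, params_for("cell_level", gamma=0.5), 100_000, rng)
    r = np.corrcoef(d1[:, 0], d1[:, 1])[0, 1]
    assert abs(r) < 0.02


def test_cell_level_gamma1_pairs_high_halves(rng):
    parent = CopyState([10, 10])
    d1, _ = sample_divisions(parent, params_for("cell_level", gamma=1.0), 20_000, rng)
    dev1 = d1[:, 0] - 10
    dev2 = d1[:, 1] - 10
    both_unequal = (dev1 != 0) & (dev2 != 0)
    assert np.all(np.sign(dev1[both_unequal]) == np.sign(dev2[both_unequal]))


def test_cell_level_tie_distribution_invariant_to_gamma(rng):
    """When the anchor splits exactly in half, pairing is a no-op: the
    other species' conditional distribution is the same for any gamma."""
    parent = CopyState([2, 10])
    out0 = sample_divisions(parent, params_for("cell_level", gamma=0.0), 200_000, rng)[0]
    out1 = sample_divisions(parent, params_for("cell_level", gamma=1.0), 200_000, rng)[0]
    tied0 = out0[out0[:, 0] == 2, 1]
    tied1 = out1[out1[:, 0] == 2, 1]
    assert stats.ks_2samp(tied0, tied1).pvalue > 0.01


def test_fraction_coupled_phi1_equal_proportions(rng):
    parent = CopyState([50, 50])
    params = params_for("fraction_coupled", coupled_fraction=1.0)
    d1, d2 = sample_divisions(parent, params, 1000, rng)
    # equal parent copies: the shared ratio maps to identical integer splits
    np.testing.assert_array_equal(d1[:, 0], d1[:, 1])
    np.testing.assert_array_equal(d2[:, 0], d2[:, 1])


@pytest.mark.parametrize("model,key,grid", [
    ("element_level", "gamma", [0.0, 0.25, 0.5, 0.75, 1.0]),
    ("cell_level", "gamma", [0.5, 0.625, 0.75, 0.875, 1.0]),
    ("fraction_coupled", "coupled_fraction", [0.0, 0.25, 0.5, 0.75, 1.0]),
])
def test_daughter_correlation_monotone_in_coupling(model, key, grid, rng):
    parent = CopyState([100, 100])
    rs = []
    for val in grid:
        d1, _ = sample_divisions(parent, params_for(model, **{key: val}), 10_000, rng)
        rs.append(np.corrcoef(d1[:, 0], d1[:, 1])[0, 1])
    diffs = np.diff(rs)
    assert np.all(diffs > -0.02), rs
    assert rs[-1] > rs[0] + 0.3


@settings(max_examples=150, deadline=None)
@given(
    n1=st.integers(min_value=0, max_value=300),
    n2=st.integers(min_value=0, max_value=300),
    coupling=st.floats(min_value=0.0, max_value=1.0),
    model=st.sampled_from(["element_level", "cell_level", "fraction_coupled"]),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_conservation_and_validity(n1, n2, coupling, model, seed):
    """Every rule conserves copies exactly and never emits negatives."""
    parent = CopyState([n1, n2])
    params = CosegParams(model=model, gamma=coupling, coupled_fraction=coupling)
    out = segregate(parent, params, np.random.default_rng(seed))
    for j in (0, 1):
        assert out.daughter1[j] >= 0 and out.daughter2[j] >= 0
        assert out.daughter1[j] + out.daughter2[j] == 2 * parent[j]
    assert np.all(out.coupled_part >= 0) and np.all(out.random_part >= 0)


def test_element_outcome_decomposition(rng):
    """Daughter copies of the coupled species decompose into the reported
    coupled + random parts."""
    parent = CopyState([10, 14])
    for _ in range(50):
        out = segregate(parent, params_for("element_level", gamma=0.6), rng)
        assert out.daughter1[1] == out.coupled_part[0] + out.random_part[0]
        assert out.daughter2[1] == out.coupled_part[1] + out.random_part[1]


def test_exchangeable_daughters(rng):
    """Marginal of daughter 1 equals that of daughter 2 (mean fraction 1/2)."""
    parent = CopyState([10, 10])
    for model, kw in [("element_level", {"gamma": 0.8}),
                      ("cell_level", {"gamma": 0.9}),
                      ("fraction_coupled", {"coupled_fraction": 0.7})]:
        d1, _ = sample_divisions(parent, params_for(model, **kw), 50_000, rng)
        frac = d1[:, 0] / 20.0
        se = frac.std() / np.sqrt(frac.shape[0])
        assert abs(frac.mean() - 0.5) < 3 * se + 1e-12


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        CosegParams(gamma=1.5)
    with pytest.raises(ValueError):
        CosegParams(coupled_fraction=-0.1)
    with pytest.raises(ValueError):
        CosegParams(model="nope")
    with pytest.raises(ValueError):
        CopyState([-1, 3])
    with pytest.raises(ValueError):
        segregate(CopyState([1, 2, 3]), CosegParams(model="element_level"),
                  np.random.default_rng(0))
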