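"""Co-abundance analysis: Spearman matrix vs independent oracles, the BY
step-up, strict edge thresholds, grouping behaviour and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gutcore.cag import (
    CoAbundanceGrouper,
    CorrelationResult,
    build_groups,
    by_adjust,
    intergroup_summary,
    significant_edges,
    spearman_matrix,
)
from tests.conftest import brute_force_by, rank_pearson


# ------------------------------------------------------------------- BY FDR


def test_by_hand_example():
    q = by_adjust([0.01, 0.02, 0.04], m=3)
    # c(3) = 11/6: q = (0.055, 0.055, 0.0733...)
    assert q == pytest.approx([0.055, 0.055, 0.0733333333], abs=1e-10)


def test_by_single_test_identity():
    assert by_adjust([0.37], m=1) == pytest.approx([0.37])


def test_by_equal_ps_equal_qs():
    q = by_adjust([0.2, 0.2, 0.2, 0.2])
    assert len(set(np.round(q, 12))) == 1


def test_by_m_smaller_than_p_is_error():
    with pytest.raises(ValueError):
        by_adjust([0.1, 0.2], m=1)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_by_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 40))
    m = int(rng.integers(k, 667))
    p = rng.random(k)
    assert by_adjust(p, m=m) == pytest.approx(brute_force_by(p, m), abs=1e-12)


def test_by_matches_statsmodels_when_family_is_observed():
    rng = np.random.default_rng(0)
    p = rng.random(50)
    ours = by_adjust(p)
    ref = multipletests(p, method="fdr_by")[1]
    assert ours == pytest.approx(ref, abs=1e-12)


# -------------------------------------------------------------- Spearman


def test_spearman_perfect_pairs():
    rel = pd.DataFrame(
        [[1, 2, 3, 4], [2, 4, 6, 9], [9, 6, 4, 1]],
        index=["up1", "up2", "down"], columns=list("abcd"), dtype=float,
    )
    corr = spearman_matrix(rel)
    i = {g: k for k, g in enumerate(corr.genera)}
    assert corr.rho[i["up1"], i["up2"]] == pytest.approx(1.0)
    assert corr.rho[i["up1"], i["down"]] == pytest.approx(-1.0)
    assert np.allclose(np.diag(corr.rho), 1.0)


def test_spearman_tied_example_matches_rank_pearson():
    x = np.array([1.0, 2.0, 2.0, 4.0])
    y = np.array([2.0, 3.0, 3.0, 5.0])
    rel = pd.DataFrame([x, y], index=["x", "y"], columns=list("abcd"))
    corr = spearman_matrix(rel)
    assert corr.rho[0, 1] == pytest.approx(rank_pearson(x, y), abs=1e-12)


def test_spearman_matches_scipy_with_zeros():
    rng = np.random.default_rng(3)
    X = rng.random((6, 30))
    X[X < 0.3] = 0.0  # zero-inflation with ties
    rel = pd.DataFrame(X, index=[f"g{i}" for i in range(6)])
    corr = spearman_matrix(rel)
    ref_rho, ref_p = stats.spearmanr(X.T)
    assert np.allclose(corr.rho, ref_rho, atol=1e-10)
    iu = np.triu_indices(6, 1)
    assert np.allclose(corr.pval[iu], ref_p[iu], atol=1e-10)


def test_spearman_constant_genus_logged():
    rel = pd.DataFrame(
        [[0.5, 0.5, 0.5, 0.5], [1, 2, 3, 4]], index=["flat", "ok"], dtype=float,
    )
    corr = spearman_matrix(rel)
    assert corr.rho[0, 1] == 0.0
    assert corr.pval[0, 1] == 1.0
    assert corr.qval[0, 1] == 1.0


def test_spearman_monotone_transform_invariance(planted_community):
    _, rel, _, truth = planted_community
    sub = rel.iloc[:8]
    c1 = spearman_matrix(sub)
    c2 = spearman_matrix(np.exp(3.0 * sub) - 0.5)
    assert np.allclose(c1.rho, c2.rho, atol=1e-12)


def test_spearman_needs_three_samples():
    with pytest.raises(ValueError):
        spearman_matrix(pd.DataFrame([[1, 2], [2, 1]], dtype=float))


# ----------------------------------------------------------------- edges


def _corr_from_rho(rho, genera, qval=None):
    rho = np.asarray(rho, dtype=float)
    k = rho.shape[0]
    q = np.full((k, k), 1e-6) if qval is None else np.asarray(qval, dtype=float)
    np.fill_diagonal(q, 0)
    return CorrelationResult(genera=list(genera), rho=rho, pval=q.copy(), qval=q)


def test_edges_strict_rho_boundary():
    rho = np.array([[1.0, 0.5], [0.5, 1.0]])
    corr = _corr_from_rho(rho, ["a", "b"])
    assert len(significant_edges(corr)) == 0  # rho == 0.5 excluded


def test_edges_signs():
    rho = np.array([[1.0, 0.9, -0.8], [0.9, 1.0, 0.1], [-0.8, 0.1, 1.0]])
    edges = significant_edges(_corr_from_rho(rho, ["a", "b", "c"]))
    signs = {(r.genus_i, r.genus_j): r.sign for r in edges.itertuples()}
    assert signs == {("a", "b"): 1, ("a", "c"): -1}


def test_edges_strict_q_boundary():
    rho = np.array([[1.0, 0.9], [0.9, 1.0]])
    q = np.full((2, 2), 0.001)
    corr = _corr_from_rho(rho, ["a", "b"], qval=q)
    assert len(significant_edges(corr)) == 0  # q == 0.001 excluded


# ---------------------------------------------------------------- grouping


def test_build_groups_block_diagonal():
    rho = np.eye(4)
    rho[0, 1] = rho[1, 0] = 0.9
    rho[2, 3] = rho[3, 2] = 0.9
    corr = _corr_from_rho(rho, list("abcd"))
    g = build_groups(corr, pd.Series([1, 0.9, 0.8, 0.7], index=list("abcd")))
    assert sorted(len(m) for m in g.groups.values()) == [2, 2]
    assert g.partition["a"] == g.partition["b"]
    assert g.partition["c"] == g.partition["d"]


def test_build_groups_all_weak_gives_singletons():
    rng = np.random.default_rng(0)
    k = 5
    noise = rng.uniform(-0.05, 0.05, size=(k, k))
    rho = np.eye(k) + (noise + noise.T) / 2
    np.fill_diagonal(rho, 1.0)
    corr = _corr_from_rho(rho, [f"g{i}" for i in range(k)])
    g = build_groups(corr, pd.Series(1.0, index=corr.genera))
    assert len(g.groups) == k


def test_group_labels_ordered_by_size_and_members_by_prevalence():
    rho = np.eye(5)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        rho[i, j] = rho[j, i] = 0.9
    rho[3, 4] = rho[4, 3] = 0.9
    prev = pd.Series([0.6, 0.9, 0.7, 1.0, 0.5], index=list("abcde"))
    g = build_groups(_corr_from_rho(rho, list("abcde")), prev)
    assert g.groups["C1"] == ["b", "c", "a"]  # biggest group, prevalence order
    assert g.groups["C2"] == ["d", "e"]


def test_grouping_permutation_invariance(planted_community):
    _, rel, _, truth = planted_community
    core = sorted(truth.core_genera)
    prev = (rel.loc[core] > 0).sum(axis=1) / rel.shape[1]
    g1 = build_groups(spearman_matrix(rel.loc[core]), prev)
    perm = list(np.random.default_rng(1).permutation(core))
    g2 = build_groups(spearman_matrix(rel.loc[perm]), prev.loc[perm])
    # identical partition as sets of member-sets
    s1 = {frozenset(m) for m in g1.groups.values()}
    s2 = {frozenset(m) for m in g2.groups.values()}
    assert s1 == s2


def test_components_mode_alternative():
    rho = np.eye(3)
    rho[0, 1] = rho[1, 0] = 0.9
    corr = _corr_from_rho(rho, list("abc"))
    g = build_groups(corr, pd.Series(1.0, index=list("abc")), mode="components")
    assert g.partition["a"] == g.partition["b"] != g.partition["c"]


# ----------------------------------------------------------- intergroup


def test_intergroup_negative_block():
    rho = np.eye(4)
    rho[0, 1] = rho[1, 0] = 0.9
    rho[2, 3] = rho[3, 2] = 0.9
    for i in (0, 1):
        for j in (2, 3):
            rho[i, j] = rho[j, i] = -0.7
    corr = _corr_from_rho(rho, list("abcd"))
    g = build_groups(corr, pd.Series([1, 0.9, 0.8, 0.7], index=list("abcd")))
    summary = intergroup_summary(g, corr)
    row = summary.iloc[0]
    assert row.mean_rho == pytest.approx(-0.7)
    assert row.n_neg_edges == 4 and row.n_pos_edges == 0


def test_intergroup_uncorrelated_singleton():
    rho = np.eye(3)
    rho[0, 1] = rho[1, 0] = 0.9
    rho[0, 2] = rho[2, 0] = 0.1
    rho[1, 2] = rho[2, 1] = -0.15
    q = np.full((3, 3), 1e-6)
    q[0, 2] = q[2, 0] = q[1, 2] = q[2, 1] = 0.5  # weak pairs not significant
    corr = _corr_from_rho(rho, list("abc"), qval=q)
    g = build_groups(corr, pd.Series(1.0, index=list("abc")))
    summary = intergroup_summary(g, corr).set_index(["group_i", "group_j"])
    pair = summary.loc[("C1", "C2")]
    assert pair.n_pos_edges == 0 and pair.n_neg_edges == 0


def test_intergroup_matches_factor_corr(planted_community):
    """Mean cross-block rho has the sign/order of the planted factor couplings."""
    _, rel, _, truth = planted_community
    core = sorted(truth.core_genera)
    prev = (rel.loc[core] > 0).sum(axis=1) / rel.shape[1]
    corr = spearman_matrix(rel.loc[core])
    idx = {g: i for i, g in enumerate(corr.genera)}

    def cross_mean(ga, gb):
        ia = [idx[g] for g, grp in truth.group_partition.items() if grp == ga]
        ib = [idx[g] for g, grp in truth.group_partition.items() if grp == gb]
        return corr.rho[np.ix_(ia, ib)].mean()

    # planted couplings: G1-G2 = +0.3, G2-G3 = -0.4, G1-G4 = -0.4
    assert cross_mean("G1", "G2") > cross_mean("G2", "G3")
    assert cross_mean("G2", "G3") < 0
    assert cross_mean("G1", "G4") < 0


# ---------------------------------------------------------------- estimator


def test_grouper_estimator(planted_community):
    _, rel, _, truth = planted_community
    core = sorted(truth.core_genera)
    X = rel.loc[core].T
    est = CoAbundanceGrouper().fit(X)
    assert len(est.labels_) == len(core)
    assert est.edges().shape[1] == 6
    # labels_ consistent with grouping_
    for g, lab in zip(core, est.labels_):
        assert est.grouping_.partition[g] == f"C{lab + 1}"
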