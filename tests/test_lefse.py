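"""Differential abundance: Kruskal-Wallis contracts, LDA effect sizes on
planted and degenerate features, selection logic and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutcore.lefse import LefseSelector, kruskal_wallis, lda_effect_size, run_lefse
from gutcore.simulate import Effect, SyntheticConfig, generate_community


def test_kw_closed_form():
    H, p = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
    assert H == pytest.approx(27 / 7, abs=1e-9)  # 3.857...
    assert p == pytest.approx(0.0495, abs=0.0005)


def test_kw_identical_values():
    H, p = kruskal_wallis([2.0] * 8, ["a"] * 4 + ["b"] * 4)
    assert H == 0.0 and p == 1.0


def test_kw_same_distribution_zero():
    vals = [1, 5, 2, 9, 1, 5, 2, 9]
    H, _ = kruskal_wallis(vals, ["a"] * 4 + ["b"] * 4)
    assert H == pytest.approx(0.0, abs=1e-9)


def test_kw_monotone_transform_invariance():
    rng = np.random.default_rng(0)
    vals = rng.random(30)
    classes = rng.integers(0, 2, 30).astype(str)
    h1, p1 = kruskal_wallis(vals, classes)
    h2, p2 = kruskal_wallis(np.exp(5 * vals), classes)
    assert h1 == pytest.approx(h2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_kw_two_class_agrees_with_ranksum():
    """Two-class KW decisions match the Wilcoxon rank-sum test >= 99%."""
    rng = np.random.default_rng(1)
    agree = 0
    n_draw = 1000
    for _ in range(n_draw):
        x = rng.standard_normal(14)
        shift = rng.choice([0.0, 1.5])
        x[7:] += shift
        classes = np.array(["a"] * 7 + ["b"] * 7)
        _, p_kw = kruskal_wallis(x, classes)
        p_rs = stats.ranksums(x[:7], x[7:]).pvalue
        agree += (p_kw < 0.05) == (p_rs < 0.05)
    assert agree / n_draw >= 0.99


def test_kw_validation():
    with pytest.raises(ValueError):
        kruskal_wallis([1, 2, 3], ["a", "a", "a"])


def test_lda_identical_feature_zero_score():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(
        {"flat": np.full(40, 1e-3), "vary": rng.random(40) * 1e-3},
        index=[f"s{i}" for i in range(40)],
    )
    classes = ["a"] * 20 + ["b"] * 20
    scores = lda_effect_size(X, classes, seed=0)
    assert scores.loc["flat", "lda_score"] == 0.0


def test_lda_planted_magnitude():
    """Per-million means 1e5 vs 1e3 with small spread: score > 2 and about
    log10 of the raw difference, enriched class = high-mean class."""
    rng = np.random.default_rng(3)
    n = 30
    a = rng.normal(1e5, 5e3, n) / 1e6  # class 'hi'
    b = rng.normal(1e3, 5e1, n) / 1e6
    X = pd.DataFrame({"g": np.concatenate([a, b])}, index=[f"s{i}" for i in range(2 * n)])
    classes = ["hi"] * n + ["lo"] * n
    scores = lda_effect_size(X, classes, seed=1)
    s = scores.loc["g", "lda_score"]
    assert s > 2.0
    assert abs(s - np.log10(9.9e4)) < 0.5
    assert scores.loc["g", "enriched"] == "hi"


def test_lda_class_relabel_symmetry():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(
        rng.random((30, 3)) * 1e-2, index=[f"s{i}" for i in range(30)],
        columns=list("abc"),
    )
    classes = np.array(["x"] * 15 + ["y"] * 15)
    s1 = lda_effect_size(X, classes, seed=5)
    s2 = lda_effect_size(X, np.where(classes == "x", "y", "x"), seed=5)
    assert np.allclose(s1["lda_score"], s2["lda_score"], atol=1e-9)


def test_lda_sample_order_determinism():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(
        rng.random((24, 4)) * 1e-2, index=[f"s{i:02d}" for i in range(24)],
        columns=list("abcd"),
    )
    classes = pd.Series(["u"] * 12 + ["v"] * 12, index=X.index)
    perm = rng.permutation(24)
    s1 = lda_effect_size(X, classes.to_numpy(), seed=9)
    s2 = lda_effect_size(X.iloc[perm], classes.iloc[perm].to_numpy(), seed=9)
    assert np.allclose(s1["lda_score"], s2["lda_score"], atol=1e-12)


def test_run_lefse_selected_subset_of_survivors():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.random((40, 10)) * 1e-2)
    classes = ["a"] * 20 + ["b"] * 20
    res = run_lefse(X, classes, seed=0)
    tab = res.table
    assert (tab.loc[tab["selected"], "passed_screen"]).all()
    assert tab.loc[~tab["passed_screen"], "lda_score"].isna().all()


def test_run_lefse_alpha_zero_blocks_everything():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.random((20, 5)))
    res = run_lefse(X, ["a"] * 10 + ["b"] * 10, alpha=0.0, seed=0)
    assert not res.table["passed_screen"].any()
    assert res.selected == []


def test_run_lefse_recovers_planted_effects():
    labels = pd.DataFrame({"grp": ["A"] * 40 + ["B"] * 40})
    offs = np.zeros(20)
    offs[:5] = -4.0
    effects = tuple(Effect(f"Genus{i+1:03d}", "grp", "B", 2.0) for i in range(5))
    cfg = SyntheticConfig(
        n_samples=80, n_genera=20, group_sizes=(), factor_corr=np.zeros((0, 0)),
        factor_loading=0.0, dropout=np.zeros(20), genus_offsets=offs,
        class_labels=labels, effects=effects, seed=17,
    )
    counts, _, _ = generate_community(cfg)
    rel = (counts / counts.sum(axis=0)).T
    res = run_lefse(rel, labels["grp"].to_numpy(), seed=17)
    planted = {f"Genus{i+1:03d}" for i in range(5)}
    assert planted <= set(res.selected)
    for g in planted:
        assert res.table.loc[g, "enriched"] == "B"


def test_selector_pipeline_compatible():
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import FunctionTransformer

    rng = np.random.default_rng(8)
    X = pd.DataFrame(
        rng.random((30, 6)) * 1e-2, columns=[f"g{i}" for i in range(6)]
    )
    X["g0"] *= np.array([5.0] * 15 + [1.0] * 15)  # strong planted feature
    y = np.array(["a"] * 15 + ["b"] * 15)
    pipe = Pipeline(
        [("identity", FunctionTransformer()), ("lefse", LefseSelector(random_state=0))]
    )
    Xt = pipe.fit_transform(X, y)
    sel = pipe.named_steps["lefse"]
    assert "g0" in set(np.array(X.columns)[sel.get_support()])
    assert Xt.shape[1] == sel.get_support().sum()
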