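"""Phylogeny: p-distances with pairwise deletion, NJ correctness on additive
matrices (with the scikit-bio NJ as independent oracle), bootstrap supports
and Newick round-trips."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from gutcore.phylogeny import (
    bipartitions,
    bootstrap_support,
    neighbor_joining,
    p_distance,
    read_newick,
    write_newick,
)


def random_additive_tree(n, rng):
    names = [f"t{i}" for i in range(n)]
    nodes = [TreeNode(name=x) for x in names]
    for nd in nodes:
        nd.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode()
        parent.length = float(rng.uniform(0.1, 1.0))
        parent.append(nodes[j])
        parent.append(nodes[i])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for nd in nodes:
        root.append(nd)
    return root


# ---------------------------------------------------------------- distances


def test_p_distance_identical():
    d = p_distance({"a": "ACGTACGT", "b": "ACGTACGT"})
    assert d["a", "b"] == 0.0


def test_p_distance_one_mismatch():
    d = p_distance({"a": "ACGT", "b": "AGGT"})
    assert d["a", "b"] == pytest.approx(0.25)


def test_p_distance_pairwise_deletion():
    d = p_distance({"a": "A-GT", "b": "ACCT"})
    assert d["a", "b"] == pytest.approx(1 / 3)  # 3 comparable sites, 1 mismatch


def test_p_distance_no_comparable_sites():
    with pytest.raises(ValueError, match="a.*b|b.*a"):
        p_distance({"a": "AC--", "b": "--GT"})


def test_jc69_correction():
    d = p_distance({"a": "AAAA" * 5, "b": "AAAG" * 5}, correction="jc69")
    p = 0.25
    expected = -0.75 * np.log(1 - 4 * p / 3)
    assert d["a", "b"] == pytest.approx(expected)


def test_unaligned_input_rejected():
    with pytest.raises(ValueError, match="aligned"):
        p_distance({"a": "ACGT", "b": "ACG"})


# ---------------------------------------------------------------------- NJ


def test_nj_two_taxa():
    tree = neighbor_joining(DistanceMatrix([[0, 0.4], [0.4, 0]], ["a", "b"]))
    td = tree.tip_tip_distances()
    assert td["a", "b"] == pytest.approx(0.4)


def test_nj_three_taxa_closed_form():
    # three-point formulas: la=(dab+dac-dbc)/2 etc.
    dm = DistanceMatrix([[0, 5, 9], [5, 0, 10], [9, 10, 0]], ["a", "b", "c"])
    tree = neighbor_joining(dm)
    lens = {t.name: t.length for t in tree.tips()}
    assert lens == pytest.approx({"a": 2.0, "b": 3.0, "c": 7.0})


def test_nj_four_taxon_example():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
    dm = DistanceMatrix(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        ["A", "B", "C", "D"],
    )
    tree = neighbor_joining(dm)
    assert bipartitions(tree) == frozenset({frozenset({"C", "D"})})
    td = tree.tip_tip_distances()
    for a, b in [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]:
        assert td[a, b] == pytest.approx(dm[a, b], abs=1e-9)


def test_nj_consistency_random_trees():
    rng = np.random.default_rng(0)
    for _ in range(60):
        n = int(rng.integers(4, 13))
        ref = random_additive_tree(n, rng)
        dm = ref.tip_tip_distances()
        tree = neighbor_joining(DistanceMatrix(dm.data, dm.ids))
        assert bipartitions(tree) == bipartitions(ref)
        td = tree.tip_tip_distances()
        out = np.array([[td[a, b] for b in dm.ids] for a in dm.ids])
        assert np.allclose(out, dm.data, atol=1e-9)


def test_nj_matches_skbio_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = int(rng.integers(4, 11))
        ref = random_additive_tree(n, rng)
        dm = ref.tip_tip_distances()
        ours = neighbor_joining(DistanceMatrix(dm.data, dm.ids))
        theirs = skbio_nj(DistanceMatrix(dm.data, dm.ids))
        assert bipartitions(ours) == bipartitions(theirs)


def test_nj_taxon_order_isomorphism():
    rng = np.random.default_rng(2)
    ref = random_additive_tree(8, rng)
    dm = ref.tip_tip_distances()
    ids = list(dm.ids)
    perm = list(rng.permutation(ids))
    data = np.array([[dm[a, b] for b in perm] for a in perm])
    t1 = neighbor_joining(DistanceMatrix(dm.data, ids))
    t2 = neighbor_joining(DistanceMatrix(data, perm))
    assert bipartitions(t1) == bipartitions(t2)


def test_nj_rejects_asymmetric():
    with pytest.raises(Exception):
        neighbor_joining(DistanceMatrix([[0, 1], [2, 0]], ["a", "b"]))


# ------------------------------------------------------------- bootstrap


def _zero_noise_alignment():
    taxa = [f"x{i}" for i in range(6)]
    cols = []
    for members, n_cols in [
        ({"x0", "x1"}, 40),
        ({"x0", "x1", "x2"}, 40),
        ({"x4", "x5"}, 40),
    ]:
        cols += [{t: ("C" if t in members else "A") for t in taxa}] * n_cols
    for t in taxa:
        cols += [{u: ("G" if u == t else "A") for u in taxa}] * 10
    return {t: "".join(c[t] for c in cols) for t in taxa}


def test_bootstrap_full_support_on_clean_signal():
    tree, supports = bootstrap_support(_zero_noise_alignment(), n_reps=200, seed=3)
    assert supports and all(s == 1.0 for s in supports.values())
    for node in tree.non_tips(include_self=False):
        if node.name:
            assert node.name == "1.000"


def test_bootstrap_determinism():
    aln = _zero_noise_alignment()
    _, s1 = bootstrap_support(aln, n_reps=50, seed=9)
    _, s2 = bootstrap_support(aln, n_reps=50, seed=9)
    assert s1 == s2


def test_bootstrap_noise_alignment_low_support():
    rng = np.random.default_rng(4)
    bases = "ACGT"
    support_sum = n_sup = 0
    for seed in range(8):
        aln = {
            f"t{i}": "".join(rng.choice(list(bases), 120)) for i in range(4)
        }
        try:
            _, sup = bootstrap_support(aln, n_reps=100, seed=seed)
        except ValueError:
            continue
        for s in sup.values():
            support_sum += s
            n_sup += 1
    assert n_sup > 0
    assert support_sum / n_sup < 0.7  # i.i.d. columns: supports near 1/3


def test_bootstrap_rejects_zero_reps():
    with pytest.raises(ValueError):
        bootstrap_support(_zero_noise_alignment(), n_reps=0)


# ---------------------------------------------------------------- newick


def test_newick_round_trip(tmp_path):
    tree, _ = bootstrap_support(_zero_noise_alignment(), n_reps=20, seed=5)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    text = path.read_text()
    assert text.count("(") == text.count(")")
    back = read_newick(path)
    assert {t.name for t in back.tips()} == {t.name for t in tree.tips()}
    assert bipartitions(back) == bipartitions(tree)
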