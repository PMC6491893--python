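"""Distance-based phylogeny of core-genus representative sequences:
p-distances from a provided alignment, classic neighbor joining, and
Felsenstein bootstrap supports.

The multiple alignment itself is consumed, not computed.  Neighbor joining
is implemented here (Q-matrix agglomeration with lowest-index tie-breaking
and non-negative branch clamping); scikit-bio supplies only the containers
(DistanceMatrix, TreeNode) and Newick serialisation.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "read_alignment",
    "p_distance",
    "neighbor_joining",
    "bipartitions",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]

_VALID = frozenset(b"ACGTU")


def read_alignment(path) -> tuple[list[str], np.ndarray]:
    """Aligned FASTA -> (ids, byte matrix of shape n_taxa x n_sites)."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if len(ids) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(ids), -1)
    return ids, arr.copy()


def _distance_from_array(
    ids: list[str], arr: np.ndarray, correction: str | None
) -> DistanceMatrix:
    n = arr.shape[0]
    valid = np.isin(arr, np.frombuffer(b"ACGTU", dtype="S1"))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / m
            if correction == "jc69":
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} between {ids[i]!r} and {ids[j]!r} "
                        "is outside the Jukes-Cantor domain"
                    )
                p = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids)


def p_distance(alignment, correction: str | None = None) -> DistanceMatrix:
    """Pairwise-deletion p-distances (optionally Jukes-Cantor corrected).

    `alignment` is a path to an aligned FASTA, a dict id->sequence, or a
    pre-parsed (ids, byte-matrix) pair.  Gap and ambiguity characters are
    excluded pairwise; a pair sharing no comparable site is an error naming
    the pair.
    """
    if correction not in (None, "jc69"):
        raise ValueError(f"unknown distance correction {correction!r}")
    if isinstance(alignment, dict):
        ids = list(alignment)
        seqs = [str(alignment[i]).upper() for i in ids]
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(ids), -1)
    elif isinstance(alignment, tuple):
        ids, arr = alignment
    else:
        ids, arr = read_alignment(alignment)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    return _distance_from_array(list(ids), np.asarray(arr), correction)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining (Saitou-Nei with the Studier-Keppler Q
    criterion).

    Deterministic: ties in Q resolve to the lowest index pair.  Negative
    branch estimates are clamped to zero with the deficit moved to the sister
    branch, so all reported lengths are non-negative.  The returned tree is
    rooted at the final trifurcation (the standard unrooted representation).
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm, dtype=float))
    ids = list(dm.ids)
    D = np.array(dm.data, dtype=float)
    nodes = [TreeNode(name=i) for i in ids]

    def join(a: TreeNode, la: float, b: TreeNode, lb: float) -> TreeNode:
        parent = TreeNode()
        a.length = max(float(la), 0.0)
        b.length = max(float(lb), 0.0)
        parent.append(a)
        parent.append(b)
        return parent

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), n)  # row-major argmin = lowest index
        if i > j:
            i, j = j, i
        d = D[i, j]
        li = 0.5 * d + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d - li
        if li < 0:
            lj, li = d, 0.0
        elif lj < 0:
            li, lj = d, 0.0
        new_node = join(nodes[i], li, nodes[j], lj)
        dn = 0.5 * (D[i] + D[j] - d)
        keep = [t for t in range(n) if t not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dn[keep][None, :]])
        last_col = np.append(dn[keep], 0.0)
        D = np.hstack([D, last_col[:, None]])
        nodes = [nodes[t] for t in keep] + [new_node]

    root = TreeNode()
    if len(nodes) == 1:
        return nodes[0]
    if len(nodes) == 2:
        d = D[0, 1]
        for node, bl in zip(nodes, (d / 2.0, d / 2.0)):
            node.length = float(bl)
            root.append(node)
        return root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = (
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    )
    for node, bl in zip(nodes, lens):
        node.length = max(float(bl), 0.0)
        root.append(node)
    return root


def bipartitions(tree: TreeNode) -> frozenset:
    """Non-trivial bipartitions of an unrooted tree, canonicalised as the
    side not containing the lexicographically smallest tip."""
    tips = sorted(t.name for t in tree.tips())
    tipset = frozenset(tips)
    ref = tips[0]
    parts = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = tipset - clade if ref in clade else clade
        if 2 <= len(side) <= len(tipset) - 2:
            parts.add(side)
    return frozenset(parts)


def bootstrap_support(
    alignment, n_reps: int = 1000, seed: int = 0, correction: str | None = None
) -> tuple[TreeNode, dict]:
    """Felsenstein bootstrap: resample alignment columns with replacement,
    rebuild the NJ tree, and map bipartition frequencies onto the
    point-estimate tree.

    Supports (fractions in [0, 1]) are stored on internal nodes as
    ``node.support`` and as 3-decimal node names for Newick export.
    Deterministic given `seed`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(alignment, dict):
        ids = list(alignment)
        seqs = [str(alignment[i]).upper() for i in ids]
        arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(ids), -1)
    elif isinstance(alignment, tuple):
        ids, arr = alignment
        arr = np.asarray(arr)
    else:
        ids, arr = read_alignment(alignment)
    ids = list(ids)
    L = arr.shape[1]

    point_tree = neighbor_joining(_distance_from_array(ids, arr, correction))
    target = bipartitions(point_tree)
    counts = {part: 0 for part in target}

    rng = np.random.default_rng(int(seed))
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = arr[:, cols]
        rep_tree = neighbor_joining(_distance_from_array(ids, rep, correction))
        rep_parts = bipartitions(rep_tree)
        for part in counts:
            if part in rep_parts:
                counts[part] += 1

    supports = {part: counts[part] / n_reps for part in counts}
    tips = sorted(t.name for t in point_tree.tips())
    ref = tips[0]
    tipset = frozenset(tips)
    for node in point_tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = tipset - clade if ref in clade else clade
        if side in supports:
            node.support = supports[side]
            node.name = f"{supports[side]:.3f}"
    return point_tree, supports


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
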