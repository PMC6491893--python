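import numpy as np
import pandas as pd
import pytest

from gutcore.io import GenusCountTable, OtuTable, to_relative
from gutcore.simulate import SyntheticConfig, generate_community


@pytest.fixture
def small_otu_table():
    counts = pd.DataFrame(
        {
            "s1": [3, 3, 50, 10000, 7],
            "s2": [3, 3, 50, 0, 7],
            "s3": [2, 2, 50, 0, 7],
            "s4": [1, 2, 50, 0, 7],
        },
        index=["otu_low", "otu_ok", "otu_big", "otu_chimera", "otu_mid"],
    )
    flags = {"otu_chimera": frozenset({"chimera"})}
    return OtuTable(counts=counts, flags=flags)


@pytest.fixture
def genus_abund():
    counts = pd.DataFrame(
        {
            "s1": [25, 25, 0],
            "s2": [10, 60, 30],
            "s3": [0, 50, 50],
        },
        index=["gA", "gB", "gC"],
    )
    residual = pd.Series([50, 0, 0], index=counts.columns)
    return to_relative(GenusCountTable(counts=counts, residual=residual))


@pytest.fixture
def planted_community():
    """101 samples x 120 genera with the five planted co-abundance blocks."""
    cfg = SyntheticConfig(
        n_samples=101, n_genera=120, group_sizes=(22, 6, 5, 3, 1), seed=42
    )
    counts, meta, truth = generate_community(cfg)
    rel = counts / counts.sum(axis=0)
    return counts, rel, meta, truth


def brute_force_by(p, m):
    """Literal BY step-up: independent oracle for the q-value computation."""
    p = np.asarray(p, dtype=float)
    k = len(p)
    c = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    q = np.empty(k)
    for pos, idx in enumerate(order):
        rank = pos + 1
        candidates = [
            min(1.0, p[order[j]] * m * c / (j + 1)) for j in range(pos, k)
        ]
        q[idx] = min(candidates)
    return q


def rank_pearson(x, y):
    """Average-rank Pearson correlation: independent Spearman oracle."""
    def avg_rank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_rank(x), avg_rank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom else np.nan
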