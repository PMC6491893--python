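"""Spearman co-abundance network over the core genera and its partition into
co-abundance groups (CAGs).

Pairwise Spearman correlations are computed across samples, the upper
triangle is FDR-adjusted with the Benjamini-Yekutieli procedure (valid under
the arbitrary dependence a correlation matrix exhibits), and an edge is
significant when |rho| > 0.5 and q < 0.001 (both strict, as printed
thresholds).  Groups are formed by average-linkage agglomeration on the
distance 1 - rho, cutting the tree at height 0.5 — i.e. clusters whose mean
within-cluster correlation is at least 0.5.  Connected components over the
significant positive edges are offered as an alternative mode for
sensitivity analysis; they cannot be the primary rule because a significant
positive edge can legitimately cross two groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from ._stats import by_adjust
from .io import GenusAbundanceTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "CoAbundanceGrouping",
    "spearman_matrix",
    "by_adjust",
    "significant_edges",
    "build_groups",
    "intergroup_summary",
    "CoAbundanceGrouper",
]


@dataclass
class CorrelationResult:
    genera: list[str]
    rho: np.ndarray  # symmetric, unit diagonal
    pval: np.ndarray
    qval: np.ndarray  # BY-adjusted over the upper triangle
    r_min: float = 0.5
    q_max: float = 0.001

    @property
    def sig_mask(self) -> np.ndarray:
        mask = (np.abs(self.rho) > self.r_min) & (self.qval < self.q_max)
        np.fill_diagonal(mask, False)
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.genera, columns=self.genera)


@dataclass
class CoAbundanceGrouping:
    """Partition of the core set into groups C1, C2, ... ordered by
    descending size (ties by mean prevalence); genera within a group are
    ordered by descending prevalence."""

    partition: dict[str, str]
    groups: dict[str, list[str]] = field(default_factory=dict)
    height: float = 0.5

    @property
    def group_ids(self) -> list[str]:
        return list(self.groups)

    def labels(self, genera: list[str]) -> np.ndarray:
        return np.array([self.partition[g] for g in genera])


def spearman_matrix(
    table,
    samples: list[str] | None = None,
    r_min: float = 0.5,
    q_max: float = 0.001,
) -> CorrelationResult:
    """All-pairs Spearman rho / p / BY-q over genera (rows) across samples.

    Ranks use midranks for ties; zeros tie among themselves at the bottom of
    the ranking, which is the natural treatment for absence.  p-values come
    from the two-sided t approximation; q-values from BY over the
    m = k(k-1)/2 upper-triangle tests.  A zero-variance genus gets rho = 0,
    p = 1 against every partner (logged), so the partition still covers it.
    """
    frame = table.rel_abund if isinstance(table, GenusAbundanceTable) else table
    if samples is not None:
        frame = frame[list(samples)]
    genera = list(frame.index)
    X = frame.to_numpy(dtype=float)
    k, n = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant genera (rho set to 0, p to 1): %s",
            ", ".join(np.array(genera)[constant][:5]),
        )
        # give constant rows harmless unit-variance placeholders, zeroed later
        ranks[constant] = np.arange(n)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pval[np.abs(rho) >= 1.0] = 0.0
    pval[constant, :] = 1.0
    pval[:, constant] = 1.0
    np.fill_diagonal(pval, 0.0)

    iu = np.triu_indices(k, 1)
    m = k * (k - 1) // 2
    q_upper = by_adjust(pval[iu], m=m)
    qval = np.ones((k, k))
    qval[iu] = q_upper
    qval = np.minimum(qval, qval.T)
    qval[iu] = q_upper  # keep exact symmetry
    qval[(iu[1], iu[0])] = q_upper
    np.fill_diagonal(qval, 0.0)
    return CorrelationResult(
        genera=genera, rho=rho, pval=pval, qval=qval, r_min=r_min, q_max=q_max
    )


def significant_edges(
    corr: CorrelationResult, r_min: float | None = None, q_max: float | None = None
) -> pd.DataFrame:
    """Edge list with |rho| > r_min and q < q_max (both strict)."""
    r_min = corr.r_min if r_min is None else r_min
    q_max = corr.q_max if q_max is None else q_max
    rows = []
    k = len(corr.genera)
    for i in range(k):
        for j in range(i + 1, k):
            r, q = corr.rho[i, j], corr.qval[i, j]
            if abs(r) > r_min and q < q_max:
                rows.append(
                    (
                        corr.genera[i],
                        corr.genera[j],
                        r,
                        corr.pval[i, j],
                        q,
                        1 if r > 0 else -1,
                    )
                )
    return pd.DataFrame(
        rows, columns=["genus_i", "genus_j", "rho", "p", "q", "sign"]
    )


def build_groups(
    corr: CorrelationResult,
    prevalences: pd.Series | dict | None = None,
    height: float = 0.5,
    mode: str = "linkage",
) -> CoAbundanceGrouping:
    """Partition the core genera into co-abundance groups.

    mode='linkage' (primary): average-linkage clustering on d = 1 - rho cut
    at `height`.  mode='components': connected components of the significant
    positive-edge graph (sensitivity analysis).
    """
    genera = corr.genera
    k = len(genera)
    if prevalences is None:
        prevalences = pd.Series(0.0, index=genera)
    elif not isinstance(prevalences, pd.Series):
        prevalences = pd.Series(dict(prevalences))
    prevalences = prevalences.reindex(genera).fillna(0.0)

    if k == 1:
        raw = np.array([1])
    elif mode == "linkage":
        d = np.clip(1.0 - corr.rho, 0.0, None)
        np.fill_diagonal(d, 0.0)
        condensed = squareform(d, checks=False)
        Z = linkage(condensed, method="average")
        raw = fcluster(Z, t=height, criterion="distance")
    elif mode == "components":
        adj = corr.sig_mask & (corr.rho > 0)
        _, raw = connected_components(adj.astype(int), directed=False)
        raw = raw + 1
    else:
        raise ValueError(f"unknown grouping mode {mode!r}")

    clusters: dict[int, list[str]] = {}
    for g, lab in zip(genera, raw):
        clusters.setdefault(int(lab), []).append(g)
    ordered = sorted(
        clusters.values(),
        key=lambda gs: (
            -len(gs),
            -float(prevalences.loc[gs].mean()),
            tuple(sorted(gs)),
        ),
    )
    groups: dict[str, list[str]] = {}
    partition: dict[str, str] = {}
    for idx, members in enumerate(ordered, start=1):
        gid = f"C{idx}"
        members = sorted(members, key=lambda g: (-float(prevalences.loc[g]), g))
        groups[gid] = members
        for g in members:
            partition[g] = gid
    return CoAbundanceGrouping(partition=partition, groups=groups, height=height)


def intergroup_summary(
    grouping: CoAbundanceGrouping, corr: CorrelationResult
) -> pd.DataFrame:
    """Mean cross-group rho and significant edge counts for every group pair."""
    pos = {g: i for i, g in enumerate(corr.genera)}
    mask = corr.sig_mask
    rows = []
    gids = grouping.group_ids
    for a_idx in range(len(gids)):
        for b_idx in range(a_idx + 1, len(gids)):
            ga, gb = gids[a_idx], gids[b_idx]
            ia = [pos[g] for g in grouping.groups[ga]]
            ib = [pos[g] for g in grouping.groups[gb]]
            sub_r = corr.rho[np.ix_(ia, ib)]
            sub_m = mask[np.ix_(ia, ib)]
            sub_sign = np.sign(corr.rho[np.ix_(ia, ib)])
            n_pos = int((sub_m & (sub_sign > 0)).sum())
            n_neg = int((sub_m & (sub_sign < 0)).sum())
            rows.append((ga, gb, float(sub_r.mean()), n_pos, n_neg))
    return pd.DataFrame(
        rows, columns=["group_i", "group_j", "mean_rho", "n_pos_edges", "n_neg_edges"]
    )


class CoAbundanceGrouper(ClusterMixin, BaseEstimator):
    """Cluster genera (features of X) into co-abundance groups.

    Note the unusual orientation for a clusterer: X is samples x genera and
    the *columns* are clustered, because co-abundance is defined across
    samples.  ``labels_`` aligns with the columns of X.

    Parameters mirror the module functions: correlation/FDR thresholds for
    edge significance, linkage cut height, and grouping mode.
    """

    def __init__(
        self,
        r_min: float = 0.5,
        q_max: float = 0.001,
        height: float = 0.5,
        mode: str = "linkage",
    ):
        self.r_min = r_min
        self.q_max = q_max
        self.height = height
        self.mode = mode

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            frame = X.T
        else:
            X = np.asarray(X, dtype=float)
            frame = pd.DataFrame(
                X.T, index=[f"g{i}" for i in range(X.shape[1])]
            )
        self.feature_names_in_ = np.asarray(frame.index, dtype=object)
        self.n_features_in_ = frame.shape[0]
        prev = (frame > 0).sum(axis=1) / frame.shape[1]
        self.correlation_ = spearman_matrix(
            frame, r_min=self.r_min, q_max=self.q_max
        )
        self.grouping_ = build_groups(
            self.correlation_, prev, height=self.height, mode=self.mode
        )
        self.labels_ = np.array(
            [int(self.grouping_.partition[g][1:]) - 1 for g in frame.index]
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def edges(self) -> pd.DataFrame:
        check_is_fitted(self, "correlation_")
        return significant_edges(self.correlation_)
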