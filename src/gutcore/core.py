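"""Prevalence-based identification of the core genus set.

A genus is core when it is detected (relative abundance > 0) in at least a
threshold fraction — by default half — of the healthy samples.  The boundary
is inclusive, matching a "present in at least 50% of samples" definition whose
minimum admitted member sits exactly at the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import GenusAbundanceTable, GenusCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "CoreSet",
    "prevalence",
    "identify_core",
    "core_summary",
    "CorePrevalenceSelector",
]


@dataclass
class CoreSet:
    """Ordered core-genus table: descending prevalence, ties broken by
    descending mean abundance then genus name."""

    entries: pd.DataFrame  # columns: genus, prevalence, mean_rel_abund
    threshold: float

    @property
    def genera(self) -> list[str]:
        return list(self.entries["genus"])

    def __len__(self) -> int:
        return len(self.entries)


def _as_frame(table) -> pd.DataFrame:
    """Accept a GenusAbundanceTable or a bare genus x sample DataFrame."""
    if isinstance(table, GenusAbundanceTable):
        return table.rel_abund
    return table


def prevalence(table, samples: Sequence[str] | None = None) -> pd.Series:
    """Fraction of the given samples in which each genus is detected (> 0)."""
    frame = _as_frame(table)
    if samples is not None:
        samples = list(samples)
        if not samples:
            raise ValueError("empty sample subset")
        frame = frame[samples]
    if frame.shape[1] == 0:
        raise ValueError("empty sample subset")
    prev = (frame > 0).sum(axis=1) / frame.shape[1]
    prev.name = "prevalence"
    return prev


def identify_core(
    prev: Mapping[str, float] | pd.Series,
    mean_abund: Mapping[str, float] | pd.Series | None = None,
    threshold: float = 0.5,
) -> CoreSet:
    """Select genera with prevalence >= threshold (inclusive) and order them."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    prev = pd.Series(dict(prev)) if not isinstance(prev, pd.Series) else prev
    if mean_abund is None:
        mean_abund = pd.Series(0.0, index=prev.index)
    elif not isinstance(mean_abund, pd.Series):
        mean_abund = pd.Series(dict(mean_abund))
    mean_abund = mean_abund.reindex(prev.index).fillna(0.0)
    keep = prev[prev >= threshold]
    if keep.empty:
        logger.warning("no genus reached prevalence %.3g: empty core set", threshold)
    entries = pd.DataFrame(
        {
            "genus": keep.index,
            "prevalence": keep.values,
            "mean_rel_abund": mean_abund.loc[keep.index].values,
        }
    )
    entries = entries.sort_values(
        by=["prevalence", "mean_rel_abund", "genus"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return CoreSet(entries=entries, threshold=threshold)


def core_summary(
    core: CoreSet,
    dataset_tables: Mapping[str, GenusCountTable],
    abundant_cutoff: float = 0.01,
    mean_abund: pd.Series | None = None,
) -> dict:
    """Fraction of total sequences held by the core genera, per dataset.

    Returns per-dataset fractions, their unweighted mean, and the pooled-read
    fraction (total core reads over total reads across datasets) — the two
    natural readings of a cross-dataset "average"; plus the core genera whose
    mean relative abundance exceeds `abundant_cutoff`.
    """
    genera = set(core.genera)
    fractions: dict[str, float] = {}
    pooled_core = pooled_total = 0.0
    for ds, table in dataset_tables.items():
        total = float(table.totals.sum())
        if total <= 0:
            raise ValueError(f"dataset {ds!r} has zero reads")
        present = [g for g in table.counts.index if g in genera]
        core_reads = float(table.counts.loc[present].to_numpy().sum())
        fractions[ds] = core_reads / total
        pooled_core += core_reads
        pooled_total += total
    if mean_abund is None:
        mean_abund = core.entries.set_index("genus")["mean_rel_abund"]
    abundant = [
        g for g in core.genera if float(mean_abund.get(g, 0.0)) > abundant_cutoff
    ]
    return {
        "per_dataset": fractions,
        "average": float(np.mean(list(fractions.values()))) if fractions else float("nan"),
        "pooled": pooled_core / pooled_total if pooled_total else float("nan"),
        "abundant_core": abundant,
    }


class CorePrevalenceSelector(TransformerMixin, BaseEstimator):
    """Feature selector retaining genera present in >= `threshold` of samples.

    Follows the scikit-learn convention: X is samples x genera.  Fit on the
    healthy cohort, then transform any cohort (healthy or diseased) down to
    the core genus columns.

    Attributes
    ----------
    prevalences_ : Series, per-genus detection fraction in the fit samples
    core_ : CoreSet
    support_ : boolean array over input columns
    """

    def __init__(self, threshold: float = 0.5):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = self._to_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.prevalences_ = prevalence(X.T)
        self.core_ = identify_core(
            self.prevalences_, X.mean(axis=0), threshold=self.threshold
        )
        members = set(self.core_.genera)
        self.support_ = np.array([g in members for g in X.columns])
        return self

    def transform(self, X):
        check_is_fitted(self, "core_")
        X = self._to_frame(X)
        return X[self.core_.genera]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    @staticmethod
    def _to_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if X.shape[0] == 0 or X.shape[1] == 0:
                raise ValueError("empty input table")
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D samples x genera array")
        return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])
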