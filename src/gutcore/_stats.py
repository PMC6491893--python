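"""Shared small statistical primitives (FDR step-up procedures)."""

from __future__ import annotations

import numpy as np


def _step_up(p: np.ndarray, m: int, c: float) -> np.ndarray:
    """Generic step-up adjustment: q_i = min_{j >= rank(i)} min(1, p_(j)*m*c/j)."""
    p = np.asarray(p, dtype=float)
    k = p.size
    if k == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    raw = ranked * m * c / np.arange(1, k + 1)
    q = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def by_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Yekutieli adjusted q-values, valid under arbitrary dependence.

    Parameters
    ----------
    p : array-like
        Raw p-values in [0, 1].
    m : int, optional
        Number of tests in the family. May exceed ``len(p)`` (degenerate tests
        counted in the family but not observed); defaults to ``len(p)``.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} is smaller than the number of p-values ({p.size})")
    c = float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 1.0
    return _step_up(p, m, c)


def bh_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (c(m) = 1)."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} is smaller than the number of p-values ({p.size})")
    return _step_up(p, m, 1.0)


def fdr_adjust(p, method: str = "bh", m: int | None = None) -> np.ndarray:
    """Dispatch to a named FDR procedure ('bh' or 'by')."""
    if method == "bh":
        return bh_adjust(p, m)
    if method == "by":
        return by_adjust(p, m)
    raise ValueError(f"unknown FDR method {method!r}")
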