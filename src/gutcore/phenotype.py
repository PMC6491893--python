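"""Spearman screen between principal-component scores and host parameters.

Each (component, parameter) pair is correlated on its pairwise-complete
samples; the whole k x m family is FDR-adjusted in one batch
(Benjamini-Hochberg by default — the dependence among a handful of PC scores
is mild, and the stricter Benjamini-Yekutieli remains available) and flagged
at q < 0.1 (strict).  Pairs with fewer than 3 complete observations are
reported as NA and excluded from the family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fdr_adjust
from .ordination import OrdinationResult

logger = logging.getLogger(__name__)

__all__ = ["correlate_pcs"]


def correlate_pcs(
    ordination,
    params: pd.DataFrame,
    k_components: int = 10,
    q_max: float = 0.1,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Spearman rho/p/q for each (PC, host parameter) pair.

    Parameters
    ----------
    ordination : OrdinationResult or samples x components DataFrame
    params : samples x parameters numeric DataFrame (NaN = missing)
    k_components : cap on the number of leading components entering the family
    """
    scores = (
        ordination.scores if isinstance(ordination, OrdinationResult) else ordination
    )
    if not scores.index.equals(params.index):
        params = params.reindex(scores.index)
    k = min(k_components, scores.shape[1])
    comps = list(scores.columns[:k])

    rows = []
    for comp in comps:
        x = scores[comp].to_numpy(dtype=float)
        for par in params.columns:
            yv = params[par].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(yv)
            n = int(ok.sum())
            if n < 3:
                logger.warning("pair (%s, %s): only %d complete pairs; NA", comp, par, n)
                rows.append((comp, par, np.nan, np.nan, n))
                continue
            rho, p = stats.spearmanr(x[ok], yv[ok])
            if not np.isfinite(rho):  # constant parameter
                rho, p = np.nan, np.nan
            rows.append((comp, par, rho, p, n))
    out = pd.DataFrame(rows, columns=["component", "parameter", "rho", "p", "n"])
    out["q"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "q"] = fdr_adjust(out.loc[valid, "p"].to_numpy(), method=fdr_method)
    out["significant"] = out["q"] < q_max
    return out
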