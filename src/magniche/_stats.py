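"""Shared rank-statistics helpers used by several modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def spearman_dissimilarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise (1 - rho)/2 dissimilarities between the rows of ``profiles``.

    rho is the Spearman rank correlation (mid-ranks for ties) over the
    shared column set.  Rows that are constant have undefined rho; their
    off-diagonal entries are set to NaN.

    Returns a symmetric DataFrame with zero diagonal, values in [0, 1].
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 entities")
    values = np.asarray(profiles, dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, values)
    constant = ranks.std(axis=1) == 0
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    diss = (1.0 - rho) / 2.0
    diss[constant, :] = np.nan
    diss[:, constant] = np.nan
    np.fill_diagonal(diss, 0.0)
    # numerical guard: corrcoef can stray a hair outside [-1, 1]
    diss = np.clip(diss, 0.0, 1.0)
    return pd.DataFrame(diss, index=profiles.index, columns=profiles.index)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho via rank-then-Pearson with mid-ranks."""
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    return float((rx * ry).sum() / denom)
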