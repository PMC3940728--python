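"""Covariate adjustment and rank-based inverse-normal transformation."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

BLOM_OFFSET = 0.375  # (rank - 3/8) / (n + 1/4)


def adjust_and_rank_transform(
    y: np.ndarray,
    X: np.ndarray | None = None,
    offset: float = BLOM_OFFSET,
) -> np.ndarray:
    """Residualise ``y`` on an intercept plus ``X``, then map average-tie
    ranks through the normal quantile of ``(rank - offset)/(n - 2*offset + 1)``.

    Rows with missing ``y`` or covariates are dropped pairwise and returned
    as ``NaN`` in the output (which is aligned to the input).
    """
    y = np.asarray(y, dtype=float)
    n_all = y.shape[0]
    if X is None:
        X = np.empty((n_all, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    yv, Xv = y[ok], X[ok]
    n = yv.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    if np.ptp(yv) == 0:
        raise ValueError("constant phenotype cannot be rank-transformed")
    design = np.column_stack([np.ones(n), Xv])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ beta
    ranks = rankdata(resid, method="average")
    z = ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    out = np.full(n_all, np.nan)
    out[ok] = z
    return out
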