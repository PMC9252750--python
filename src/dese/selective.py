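"""Selective-expression scoring (robust regression Z-scores, REZ).

A gene is selectively expressed in a tissue or cell type when its level
there stands out from its level everywhere else. For each panel column
t, the log expression x = log2(CPM_t + 1) is regressed on the
leave-one-out baseline m = per-gene median of log2(CPM + 1) over all
other columns, using a Huber-weighted robust fit so that the handful of
genuinely selective genes does not drag the trend line toward
themselves. The REZ score is the residual standardized by a robust
scale, z = (x - fit(m)) / (1.4826 * MAD of residuals).

The exact regression design of the original REZ formulation is not
restated in the source describing this pipeline; the leave-one-out
median baseline and Huber IRLS used here are a declared reconstruction
(see docs/methods.md).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import median_abs_deviation

from .errors import NotEnoughColumns
from .panel import ExpressionPanel

logger = logging.getLogger(__name__)

HUBER_T = 1.345
MAX_ITER = 50
TOL = 1e-8


def rez_scores(
    panel: ExpressionPanel | pd.DataFrame,
    huber_t: float = HUBER_T,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> pd.DataFrame:
    """Gene x column matrix of robust-regression selective-expression Z.

    Requires at least 3 columns and 10 genes. A column whose residuals
    have zero robust scale (e.g. all panel columns identical) gets z = 0
    with a warning rather than an undefined division.
    """
    values = panel.values if isinstance(panel, ExpressionPanel) else panel
    if values.shape[1] < 3:
        raise NotEnoughColumns("REZ needs at least 3 panel columns")
    if values.shape[0] < 10:
        raise NotEnoughColumns("REZ needs at least 10 genes")

    log_expr = np.log2(values.to_numpy(float) + 1.0)
    n_genes, n_cols = log_expr.shape
    z = np.zeros_like(log_expr)

    for t in range(n_cols):
        x = log_expr[:, t]
        others = np.delete(log_expr, t, axis=1)
        m = np.median(others, axis=1)
        resid = _robust_residuals(x, m, huber_t, max_iter, tol)
        scale = median_abs_deviation(resid, scale="normal")
        # Zero MAD means more than half the residuals vanish. If a few
        # genes still carry real residuals (a lone selective gene on an
        # otherwise noise-free panel) fall back to the residual SD so
        # they keep a finite score; only a fully perfect fit gives z=0.
        if scale < 1e-9:
            scale = float(np.std(resid))
        if scale < 1e-9:
            logger.warning(
                "column %s: zero residual scale, selective-expression z set to 0",
                values.columns[t],
            )
            continue
        z[:, t] = resid / scale
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def _robust_residuals(
    x: np.ndarray, m: np.ndarray, huber_t: float, max_iter: int, tol: float
) -> np.ndarray:
    """Residuals of a Huber IRLS fit of x on [1, m].

    Falls back to ordinary least squares when the design is degenerate
    (constant baseline) or the fit is already perfect, where the robust
    and ordinary solutions coincide.
    """
    design = sm.add_constant(m, has_constant="add")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    ols_resid = x - design @ beta
    if np.ptp(m) == 0 or float(np.max(np.abs(ols_resid))) < 1e-10:
        return ols_resid
    fit = sm.RLM(x, design, M=sm.robust.norms.HuberT(t=huber_t)).fit(
        maxiter=max_iter, tol=tol
    )
    return np.asarray(fit.resid)
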