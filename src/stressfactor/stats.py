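"""Shared statistical helpers: FDR adjustment and variance moderation."""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

_MAX_PRIOR_DF = 1.0e6


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``p_adj(i) = min_{j >= i} (m * p(j) / j)`` over ascending-sorted
    p-values, clipped at 1.  One adjustment family per call.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, monotone decreasing)."""
    if x <= 0:
        return np.inf
    # trigamma(y) ~ 1/y + 1/(2y^2); start from the 1/y asymptote
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-variable residual variances toward a common prior.

    Method-of-moments fit of a scaled inverse chi-square prior on the
    log-variances: with ``e_g = log(s2_g) - digamma(df/2) + log(df/2)``,
    the excess spread ``var(e) - trigamma(df/2)`` identifies the prior
    degrees of freedom ``d0`` through ``trigamma(d0/2)``, and ``mean(e)``
    identifies the prior variance ``s0^2``.  Returns
    ``(s2_tilde, s0^2, d0)`` where
    ``s2_tilde = (d0*s0^2 + df*s2) / (d0 + df)``.

    When the observed spread does not exceed the theoretical chi-square
    spread, the prior is effectively infinite; ``d0`` is capped at 1e6 and
    every moderated variance collapses to the prior.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < 0) or not np.all(np.isfinite(s2)):
        raise ValueError("residual variances must be finite and non-negative")
    if s2.size < 2:
        raise ValueError("need at least two variables to estimate a prior")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        d0 = min(d0, _MAX_PRIOR_DF)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = _MAX_PRIOR_DF
        s0_sq = float(np.exp(e_mean))
    s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
    return s2_tilde, s0_sq, d0
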