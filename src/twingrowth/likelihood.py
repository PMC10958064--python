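"""Censored Student-t observation model.

Right-censoring at the response ceiling is handled by integrating the
censored observations out: a censored record contributes the upper-tail
probability P(Y >= U) instead of a density value.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def log_likelihood_term(
    y: float | np.ndarray,
    mu: float | np.ndarray,
    sigma: float,
    nu: float,
    censored: bool | np.ndarray = False,
    bound: float | None = None,
) -> np.ndarray:
    """Per-observation log-likelihood under a location-scale Student-t.

    Uncensored observations contribute the t density of ``(y - mu)/sigma``
    with the scale Jacobian; censored ones contribute the log survival
    probability ``log P(Y >= bound | mu, sigma, nu)``.  A censored flag on a
    record whose value differs from the bound is a data inconsistency and is
    rejected.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if nu <= 2:
        raise ValueError("t degrees of freedom must exceed 2")
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape) if y.shape else mu
    cens = np.broadcast_to(np.asarray(censored, dtype=bool), y.shape)
    if cens.any():
        if bound is None:
            raise ValueError("censored observations require the bound")
        if not np.allclose(np.asarray(y)[cens], bound):
            raise ValueError("censored flag set but value differs from the bound")
    out = stats.t.logpdf(y, df=nu, loc=mu, scale=sigma)
    if cens.any():
        tail = stats.t.logsf(bound, df=nu, loc=mu, scale=sigma)
        out = np.where(cens, tail, out)
    return out
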