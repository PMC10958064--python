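"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: tail probabilities
by adaptive quadrature of the t density, variance components by a nested
method-of-moments (ANOVA) decomposition, and regression coefficients by
plain normal equations.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def t_tail_by_quadrature(bound: float, mu: float, sigma: float, nu: float) -> float:
    """P(Y >= bound) for Y ~ t_nu(mu, sigma) by adaptive quadrature."""

    def dens(x):
        z = (x - mu) / sigma
        return stats.t.pdf(z, df=nu) / sigma

    upper = mu + 60.0 * sigma
    val, _ = integrate.quad(dens, bound, upper, epsabs=1e-13, epsrel=1e-12)
    # add the analytic remainder beyond the numeric window
    z = (upper - mu) / sigma
    return val + float(stats.t.sf(z, df=nu))


def mom_variance_shares(trials, n_trials_per_cell: int | None = None):
    """Nested method-of-moments decomposition of a balanced twin design.

    Levels: trial < occasion (individual x wave) < individual < family.
    Returns shares (wave, individual, family, residual) of total variance.
    Requires full retention and two individuals per family.
    """
    t = trials[trials["condition"].isin(("negative", "neutral"))].copy()
    t["y"] = t["duration_ms"] / 1000.0
    cell = t.groupby(["family_id", "individual_id", "wave"])["y"].agg(
        ["mean", "var", "count"]
    )
    V_e = cell["var"].mean()
    nt = (
        n_trials_per_cell
        if n_trials_per_cell is not None
        else int(cell["count"].iloc[0])
    )
    n_waves = cell.groupby(["family_id", "individual_id"]).size().iloc[0]
    ind = cell.groupby(["family_id", "individual_id"])["mean"].agg(["mean", "var"])
    V_w = ind["var"].mean() - V_e / nt
    fam = ind.groupby("family_id")["mean"].agg(["mean", "var"])
    V_u = fam["var"].mean() - V_w / n_waves - V_e / (n_waves * nt)
    V_v = (
        fam["mean"].var()
        - V_u / 2
        - V_w / (2 * n_waves)
        - V_e / (2 * n_waves * nt)
    )
    total = V_e + V_w + V_u + V_v
    return {
        "occasion": V_w / total,
        "individual": V_u / total,
        "family": V_v / total,
        "residual": V_e / total,
    }


def ols_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with intercept via the normal equations."""
    Xd = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
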