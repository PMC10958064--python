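"""Saturated multivariate regression per plausible-value set, pooled by
Rubin's rules with the Barnard-Rubin degrees-of-freedom adjustment.

Each of the m plausible-value sets supplies the 12 individual growth
components (4 outcomes x intercept/linear/quadratic) as predictors of the
five well-being subscales.  The predictors covary freely (12 variances +
66 covariances) and all outcome residuals covary freely, so the model is
saturated: T = 0, df = 0, and the ML coefficients equal per-outcome least
squares.  Estimates and squared standard errors are then combined across
sets:

    Qbar = mean(Q_s);  Wbar = mean(SE_s^2);  B = var(Q_s, ddof=1)
    T_var = Wbar + (1 + 1/m) B
    gamma = (1 + 1/m) B / T_var            (fraction missing information)
    nu_R = (m - 1) / gamma^2
    nu_obs = ((nu_com+1)/(nu_com+3)) * nu_com * (1 - gamma)
    df = (1/nu_R + 1/nu_obs)^-1            (Barnard-Rubin)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import COMPONENTS, OUTCOMES

PREDICTORS = tuple(f"{o}_{c}" for o in OUTCOMES for c in COMPONENTS)


def count_free_covariances(n_predictors: int) -> int:
    """Free covariances among n freely-covarying predictors: n(n-1)/2."""
    if n_predictors < 2:
        return 0
    return n_predictors * (n_predictors - 1) // 2


@dataclass
class DrawFit:
    """Saturated-model ML fit for one plausible-value set."""

    draw_index: int
    n_obs: int
    coef: pd.DataFrame  # predictors x outcomes
    coef_se: pd.DataFrame
    psi_x: pd.DataFrame  # ML covariance of predictors
    psi_x_se: pd.DataFrame
    resid_cov: pd.DataFrame  # outcomes x outcomes (ML)
    statistic: float = 0.0  # saturated
    df: int = 0

    def parameters(self) -> pd.DataFrame:
        """Long table of (parameter, est, se) covering both report aims."""
        rows = []
        preds = list(self.psi_x.index)
        for i, a in enumerate(preds):
            for b in preds[i + 1:]:
                rows.append((f"cov[{a},{b}]", self.psi_x.loc[a, b],
                             self.psi_x_se.loc[a, b]))
        for out in self.coef.columns:
            for pred in self.coef.index:
                rows.append((f"beta[{out}~{pred}]", self.coef.loc[pred, out],
                             self.coef_se.loc[pred, out]))
        return pd.DataFrame(rows, columns=["parameter", "est", "se"])


def fit_sem_draw(
    pv_set: pd.DataFrame,
    outcomes: pd.DataFrame,
    draw_index: int = 0,
) -> DrawFit:
    """Fit the saturated multivariate regression for one plausible-value set.

    ``pv_set`` has one row per individual with the 12 predictor columns;
    ``outcomes`` holds the subscale scores (or factor scores).  Cases are
    listwise complete on predictors and outcomes.  ML estimates: per-outcome
    OLS coefficients, N-denominator covariance matrices, information-matrix
    standard errors.
    """
    out_cols = [c for c in outcomes.columns if c != "individual_id"]
    merged = pv_set.merge(outcomes, on="individual_id", how="inner").dropna(
        subset=list(PREDICTORS) + out_cols
    )
    n = len(merged)
    n_pred = len(PREDICTORS)
    if n <= n_pred + 1:
        raise ValueError(
            f"only {n} complete cases for {n_pred} predictors; need more"
        )
    X = merged[list(PREDICTORS)].to_numpy(dtype=float)
    Y = merged[out_cols].to_numpy(dtype=float)

    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < n_pred:
        _, R = np.linalg.qr(X - X.mean(axis=0))
        dep = [PREDICTORS[j] for j in range(n_pred) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient predictors; collinear components: {dep}")

    Xd = np.column_stack([np.ones(n), X])
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    B = XtX_inv @ Xd.T @ Y  # (1+p, q) incl. intercept row
    resid = Y - Xd @ B
    resid_cov = resid.T @ resid / n  # ML (N denominator)
    # ML SEs: sigma^2_ML * (X'X)^-1 diagonal, per outcome
    se = np.sqrt(np.outer(np.diag(XtX_inv), np.diag(resid_cov)))

    psi_x = np.cov(X, rowvar=False, ddof=0)
    # asymptotic SE of a normal-theory covariance: (s_ii s_jj + s_ij^2)/N
    psi_se = np.sqrt(
        (np.outer(np.diag(psi_x), np.diag(psi_x)) + psi_x**2) / n
    )

    preds = list(PREDICTORS)
    return DrawFit(
        draw_index=draw_index,
        n_obs=n,
        coef=pd.DataFrame(B[1:], index=preds, columns=out_cols),
        coef_se=pd.DataFrame(se[1:], index=preds, columns=out_cols),
        psi_x=pd.DataFrame(psi_x, index=preds, columns=preds),
        psi_x_se=pd.DataFrame(psi_se, index=preds, columns=preds),
        resid_cov=pd.DataFrame(resid_cov, index=out_cols, columns=out_cols),
    )


def pool_rubin(
    estimates: np.ndarray,
    standard_errors: np.ndarray,
    nu_com: float | None = None,
) -> pd.DataFrame:
    """Pool m draws of parameter estimates and SEs by Rubin's rules.

    ``estimates`` and ``standard_errors`` are (m, k) arrays; rows are
    draws.  ``nu_com`` is the complete-data degrees of freedom for the
    Barnard-Rubin adjustment; ``None`` uses the unadjusted large-sample df
    (m-1)/gamma^2.
    """
    Q = np.atleast_2d(np.asarray(estimates, dtype=float))
    SE = np.atleast_2d(np.asarray(standard_errors, dtype=float))
    m = Q.shape[0]
    if m < 2:
        raise ValueError("pooling requires m >= 2 draws (between-variance undefined)")
    if Q.shape != SE.shape:
        raise ValueError("estimates and standard_errors shapes differ")

    qbar = Q.mean(axis=0)
    wbar = (SE**2).mean(axis=0)
    b = Q.var(axis=0, ddof=1)
    t_var = wbar + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(t_var > 0, (1.0 + 1.0 / m) * b / t_var, 0.0)
        nu_r = np.where(gamma > 0, (m - 1) / gamma**2, np.inf)
        if nu_com is None:
            df = nu_r
        else:
            nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - gamma)
            df = 1.0 / (1.0 / nu_r + 1.0 / nu_obs)
        se_pool = np.sqrt(t_var)
        t_stat = np.where(se_pool > 0, qbar / se_pool, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t_stat), np.where(np.isfinite(df), df, 1e12))
    return pd.DataFrame({
        "estimate": qbar,
        "within_var": wbar,
        "between_var": b,
        "total_var": t_var,
        "se": se_pool,
        "gamma": gamma,
        "df": df,
        "t": t_stat,
        "p": p,
    })


def pool_draw_fits(fits: list[DrawFit], nu_com: float | None = None) -> pd.DataFrame:
    """Rubin-pool every parameter of a list of saturated-model fits."""
    if len(fits) < 2:
        raise ValueError("pooling requires at least two draw fits")
    tables = [f.parameters() for f in fits]
    names = tables[0]["parameter"]
    for t in tables[1:]:
        if not names.equals(t["parameter"]):
            raise ValueError("draw fits supply different parameter sets")
    Q = np.stack([t["est"].to_numpy() for t in tables])
    SE = np.stack([t["se"].to_numpy() for t in tables])
    pooled = pool_rubin(Q, SE, nu_com=nu_com)
    pooled.insert(0, "parameter", names.to_numpy())
    return pooled


def pooled_report(pooled: pd.DataFrame, alpha: float = 0.05):
    """Split pooled results into the covariance and regression tables.

    Returns ``(covariances, regressions)``: the 66 pooled predictor
    covariances and the 60 pooled regression coefficients (12 predictors x
    5 subscales under the separate-subscales branch), each with pooled SE,
    t, df, p and a significance flag at ``alpha``.
    """
    tab = pooled.copy()
    tab["significant"] = tab["p"] < alpha
    is_cov = tab["parameter"].str.startswith("cov[")
    return tab[is_cov].reset_index(drop=True), tab[~is_cov].reset_index(drop=True)
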