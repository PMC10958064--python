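"""Well-being subscale scoring and one-factor confirmatory factor analysis.

The five social well-being subscales (AWP, WHO, SC, CF, GS) are mean item
scores on a 1-4 response scale.  A one-factor CFA with marker scaling
(first loading fixed to 1) is fitted by maximum likelihood, minimizing the
Wishart discrepancy

    F_ML(S, Sigma) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - 5,

giving the chi-square test statistic T = (N-1) F_ML on df = 5, plus CFI,
TLI and RMSEA.  The fit indices drive the analysis branching rule: a
well-fitting one-factor model lets the growth components predict a common
well-being factor, a misfitting one routes them to the five subscales
separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import SUBSCALES

DF_MODEL = 5  # 15 moments - 10 free parameters
DF_BASELINE = 10


@dataclass
class CfaThresholds:
    """Branch-rule cutoffs; pass requires all three (ties pass)."""

    min_cfi: float = 0.95
    min_tli: float = 0.95
    max_rmsea: float = 0.06


@dataclass
class CfaFit:
    loadings: np.ndarray  # (5,), first fixed to 1
    uniquenesses: np.ndarray  # (5,)
    psi: float
    se: pd.DataFrame  # parameter, est, se, ci_low, ci_high
    fmin: float
    statistic: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    n_obs: int
    heywood: bool
    converged: bool
    log: str = ""

    def implied_cov(self) -> np.ndarray:
        lam = self.loadings
        return self.psi * np.outer(lam, lam) + np.diag(self.uniquenesses)

    def factor_scores(self, scores: pd.DataFrame) -> pd.DataFrame:
        """Regression-method factor scores for complete cases; used by the
        common-factor branch of the downstream SEM."""
        return regression_factor_scores(
            self.loadings, self.uniquenesses, self.psi, scores
        )


def score_subscales(
    items: pd.DataFrame,
    scoring_map: dict[str, list[str]],
    reverse_coded: Optional[set[str]] = None,
    min_answered: float | dict[str, float] = 0.8,
) -> pd.DataFrame:
    """Mean-score subscales from item responses on a 1-4 scale.

    A subscale score is the mean of answered items when at least
    ``min_answered`` of its items were answered, otherwise missing.
    Reverse-coded items are flipped (5 - x) before averaging.
    """
    reverse_coded = reverse_coded or set()
    out = {"individual_id": items["individual_id"].to_numpy()}
    for sub, cols in scoring_map.items():
        block = items[cols].astype(float).copy()
        bad = ((block < 1) | (block > 4)) & block.notna()
        if bad.any().any():
            raise ValueError(
                f"subscale {sub}: responses outside the 1-4 scale in "
                f"columns {list(block.columns[bad.any()])}"
            )
        for c in cols:
            if c in reverse_coded:
                block[c] = 5.0 - block[c]
        frac = block.notna().mean(axis=1)
        need = min_answered[sub] if isinstance(min_answered, dict) else min_answered
        score = block.mean(axis=1)
        score[frac < need] = np.nan
        out[sub] = score.to_numpy()
    return pd.DataFrame(out)


def regression_factor_scores(loadings, uniquenesses, psi,
                             scores: pd.DataFrame) -> pd.DataFrame:
    """f_hat = psi * lambda' Sigma^-1 (x - xbar) on complete cases."""
    lam = np.asarray(loadings, dtype=float)
    sigma = psi * np.outer(lam, lam) + np.diag(np.asarray(uniquenesses))
    data = scores[["individual_id"] + list(SUBSCALES)].dropna()
    x = data[list(SUBSCALES)].to_numpy(dtype=float)
    weights = psi * np.linalg.solve(sigma, lam)
    return pd.DataFrame({
        "individual_id": data["individual_id"].to_numpy(),
        "wellbeing_factor": (x - x.mean(axis=0)) @ weights,
    })


def _fml(S, lam_free, theta, psi):
    lam = np.concatenate([[1.0], lam_free])
    Sigma = psi * np.outer(lam, lam) + np.diag(theta)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf, None
    _, logdet_s = np.linalg.slogdet(S)
    val = logdet + float(np.trace(S @ np.linalg.inv(Sigma))) - logdet_s - S.shape[0]
    return val, Sigma


def _unpack(x):
    return x[:4], x[4:9], x[9]


def _objective(x, S):
    lam_free, theta, psi = _unpack(x)
    val, Sigma = _fml(S, lam_free, theta, psi)
    if not np.isfinite(val):
        return 1e10, np.zeros_like(x)
    lam = np.concatenate([[1.0], lam_free])
    Si = np.linalg.inv(Sigma)
    G = Si @ (Sigma - S) @ Si  # dF/dSigma
    g_lam = 2.0 * psi * (G @ lam)[1:]
    g_theta = np.diag(G)
    g_psi = float(lam @ G @ lam)
    return val, np.concatenate([g_lam, g_theta, [g_psi]])


def fit_one_factor_cfa(
    scores: Optional[pd.DataFrame] = None,
    *,
    sample_cov: Optional[np.ndarray] = None,
    n_obs: Optional[int] = None,
    statistic_multiplier: str = "n-1",
) -> CfaFit:
    """ML one-factor CFA of the five subscales with marker scaling.

    Accepts either a scores table (listwise deletion on the five subscale
    columns) or a sample covariance matrix with its N.  ``statistic
    multiplier`` selects the classic Wishart (N-1) or the normal-theory N
    convention for T.
    """
    if sample_cov is None:
        if scores is None:
            raise ValueError("provide scores or sample_cov")
        data = scores[list(SUBSCALES)].dropna()
        n_obs = len(data)
        if n_obs <= 10:
            raise ValueError("N must exceed the free parameter count (10)")
        sample_cov = np.cov(data.to_numpy(), rowvar=False, ddof=1)
    S = np.asarray(sample_cov, dtype=float)
    if S.shape != (5, 5):
        raise ValueError("exactly 5 subscales are required")
    if n_obs is None:
        raise ValueError("n_obs is required with sample_cov input")

    # starting values from the marker indicator's covariances
    psi0 = max(abs(S[0, 1]), 0.2 * S[0, 0], 1e-3)
    lam0 = np.clip(S[0, 1:] / psi0, -5, 5)
    lam_full0 = np.concatenate([[1.0], lam0])
    theta0 = np.maximum(np.diag(S) - psi0 * lam_full0**2, 0.1 * np.diag(S))
    x0 = np.concatenate([lam0, theta0, [psi0]])
    bounds = [(-np.inf, np.inf)] * 4 + [(0.0, np.inf)] * 5 + [(1e-10, np.inf)]

    res = optimize.minimize(
        _objective, x0, args=(S,), jac=True, method="L-BFGS-B",
        bounds=bounds, options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.fun > 1e-8:
        grad_norm = float(np.linalg.norm(res.jac))
        if grad_norm > 1e-5:
            raise RuntimeError(
                f"CFA optimizer failed to converge: {res.message}; "
                f"F={res.fun:.6g}, |grad|={grad_norm:.3g}"
            )
    lam_free, theta, psi = _unpack(res.x)
    heywood = bool(np.any(theta <= 1e-8))
    if heywood:
        warnings.warn(
            "Heywood case: a uniqueness reached its zero bound; estimates "
            "are from the boundary-constrained fit"
        )
    fmin = float(res.fun)

    mult = (n_obs - 1) if statistic_multiplier == "n-1" else n_obs
    T = mult * fmin
    p = float(stats.chi2.sf(T, DF_MODEL))

    # baseline (independence) model: Sigma = diag(S)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    f_base = -float(np.linalg.slogdet(R)[1])
    T_base = mult * f_base
    num = max(T - DF_MODEL, 0.0)
    cfi = 1.0 - num / max(T_base - DF_BASELINE, num, np.finfo(float).tiny)
    base_ratio = T_base / DF_BASELINE
    tli = (base_ratio - T / DF_MODEL) / (base_ratio - 1.0)
    rmsea = float(np.sqrt(num / (DF_MODEL * (n_obs - 1))))

    # SEs from the inverse observed information, (2/(N-1)) H^-1
    H = _numeric_hessian(lambda x: _objective(x, S)[1], res.x)
    names = (
        [f"lambda_{s}" for s in SUBSCALES[1:]]
        + [f"theta_{s}" for s in SUBSCALES]
        + ["psi"]
    )
    try:
        acov = np.linalg.inv((n_obs - 1) / 2.0 * H)
        se = np.sqrt(np.maximum(np.diag(acov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(10, np.nan)
    est = res.x
    se_tab = pd.DataFrame({
        "parameter": names,
        "est": est,
        "se": se,
        "ci_low": est - 1.959964 * se,
        "ci_high": est + 1.959964 * se,
    })

    return CfaFit(
        loadings=np.concatenate([[1.0], lam_free]),
        uniquenesses=theta,
        psi=float(psi),
        se=se_tab,
        fmin=fmin,
        statistic=float(T),
        df=DF_MODEL,
        p_value=p,
        cfi=float(cfi),
        tli=float(tli),
        rmsea=rmsea,
        n_obs=int(n_obs),
        heywood=heywood,
        converged=bool(res.success or np.linalg.norm(res.jac) <= 1e-5),
        log=str(res.message),
    )


def _numeric_hessian(grad_fn, x, eps=1e-5):
    p = len(x)
    H = np.zeros((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = eps * max(1.0, abs(x[j]))
        gp = grad_fn(x + step)
        gm = grad_fn(x - step)
        H[:, j] = (gp - gm) / (2 * step[j])
    return (H + H.T) / 2.0


def branch_on_fit(
    fit: CfaFit,
    thresholds: Optional[CfaThresholds] = None,
) -> str:
    """Decide the downstream SEM structure from the CFA fit indices.

    Returns ``"common_factor"`` when CFI, TLI and RMSEA all meet their
    cutoffs (boundary values pass), else ``"separate_subscales"``.
    """
    thresholds = thresholds or CfaThresholds()
    ok = (
        fit.cfi >= thresholds.min_cfi
        and fit.tli >= thresholds.min_tli
        and fit.rmsea <= thresholds.max_rmsea
    )
    return "common_factor" if ok else "separate_subscales"
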