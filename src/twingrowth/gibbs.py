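"""Gibbs sampler for hierarchical linear models with Student-t residuals
and right-censored responses.

The observation model is

    y_i = x_i' beta + sum_g z_{g,i}' b_{g, group_g(i)} + e_i,
    e_i ~ Student-t(nu, 0, sigma),   y_i right-censored at U for flagged rows,

with a multivariate normal random-effect vector per group in each grouping
block g, b_{g,j} ~ N(0, Sigma_g).  Sampling uses two standard data
augmentations that make every conditional conjugate:

* the Student-t as a scale mixture of normals, e_i | w_i ~ N(0, sigma^2/w_i),
  w_i ~ Gamma(nu/2, nu/2), with nu updated by griddy Gibbs on a log grid;
* censored responses imputed from the truncated normal above the bound
  given the current mixture weights.

Priors are weakly informative and conjugate: a flat-scale normal on the
fixed effects, inverse-gamma on scalar variances and the residual variance,
inverse-Wishart on multivariate random-effect covariance blocks, and a
shifted Gamma(2, scale 10) on nu - 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class REBlock:
    """One grouping level: design columns ``Z`` and row-to-group index."""

    name: str
    Z: np.ndarray  # (n, d)
    index: np.ndarray  # (n,) int in [0, n_groups)
    n_groups: int
    labels: Optional[np.ndarray] = None  # (n_groups,) group identifiers
    store_groups: bool = False  # keep per-group draws (memory!)
    #: X columns identical to this block's Z columns; enables the
    #: FE/RE translation (recentering) move that fixes slow intercept mixing
    fe_cols: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[0] != self.index.shape[0]:
            raise ValueError(f"block {self.name}: Z and index length differ")

    @property
    def dim(self) -> int:
        return self.Z.shape[1]


@dataclass
class Priors:
    fe_scale: float = 10.0  # FE sd = fe_scale * sd(y)
    var_a: float = 0.001  # inverse-gamma shape for scalar variances
    var_b: float = 0.001  # inverse-gamma rate
    iw_scale: float = 0.01  # inverse-Wishart scale matrix multiplier
    nu_shape: float = 2.0  # Gamma prior on (nu - 2)
    nu_scale: float = 10.0


def _group_crossprods(Z, idx, w, r, n_groups):
    """Per-group Z'WZ (G,d,d) and Z'Wr (G,d) via bincount."""
    d = Z.shape[1]
    A = np.empty((n_groups, d, d))
    rhs = np.empty((n_groups, d))
    for k in range(d):
        rhs[:, k] = np.bincount(idx, weights=Z[:, k] * w * r, minlength=n_groups)
        for l in range(k, d):
            v = np.bincount(idx, weights=Z[:, k] * Z[:, l] * w, minlength=n_groups)
            A[:, k, l] = v
            A[:, l, k] = v
    return A, rhs


def _slice_sample_1d(logf, x0, width, rng, max_steps=50):
    """Neal's stepping-out slice sampler for a 1-d log density."""
    logy = logf(x0) + np.log(rng.uniform())
    lo = x0 - width * rng.uniform()
    hi = lo + width
    for _ in range(max_steps):
        if logf(lo) <= logy:
            break
        lo -= width
    for _ in range(max_steps):
        if logf(hi) <= logy:
            break
        hi += width
    for _ in range(max_steps):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _sample_truncated_normal_above(mu, sd, lower, rng):
    """Draw from N(mu, sd^2) truncated to [lower, inf), numerically safe."""
    alpha = (lower - mu) / sd
    p_tail = stats.norm.sf(alpha)
    p_tail = np.clip(p_tail, 1e-290, 1.0)
    q = rng.uniform(size=np.shape(mu))
    x = mu + sd * stats.norm.isf(q * p_tail)
    # in the far tail the draw degenerates to the bound itself
    return np.where(np.isfinite(x), np.maximum(x, lower), lower)


def sample_hierarchical(
    y: np.ndarray,
    X: np.ndarray,
    blocks: Sequence[REBlock],
    censored: Optional[np.ndarray] = None,
    bound: Optional[float] = None,
    family: str = "student_t",
    chains: int = 2,
    warmup: int = 500,
    draws: int = 500,
    thin: int = 1,
    seed: int = 0,
    priors: Optional[Priors] = None,
    nestings: Optional[Sequence[tuple[str, str, np.ndarray]]] = None,
) -> dict:
    """Run the Gibbs sampler; returns raw per-chain draws.

    Output dict keys: ``beta`` (C,S,p), ``sigma`` (C,S), ``nu`` (C,S),
    ``Sigma[name]`` (C,S,d,d), and for blocks with ``store_groups``
    ``groups[name]`` (C,S,G,d), plus bookkeeping fields.
    """
    priors = priors or Priors()
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    cens = (
        np.zeros(n, dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    if cens.any() and bound is None:
        raise ValueError("censored rows require a bound")
    student = family == "student_t"
    if family not in ("student_t", "gaussian"):
        raise ValueError(f"unknown residual family {family!r}")

    sd_y = float(np.std(y)) if n > 1 else 1.0
    sd_y = sd_y if sd_y > 0 else 1.0
    fe_prec = 1.0 / (priors.fe_scale * sd_y) ** 2

    block_pos = {b.name: i for i, b in enumerate(blocks)}
    for child_name, parent_name, c2p in (nestings or ()):
        bc, bp = blocks[block_pos[child_name]], blocks[block_pos[parent_name]]
        if bc.dim != bp.dim:
            raise ValueError("nested blocks must share design dimension")
        if len(c2p) != bc.n_groups:
            raise ValueError("nesting map must cover every child group")

    out = {
        "beta": np.empty((chains, draws, p)),
        "sigma": np.empty((chains, draws)),
        "nu": np.empty((chains, draws)),
        "Sigma": {b.name: np.empty((chains, draws, b.dim, b.dim)) for b in blocks},
        "groups": {
            b.name: np.empty((chains, draws, b.n_groups, b.dim))
            for b in blocks
            if b.store_groups
        },
        "block_labels": {b.name: b.labels for b in blocks},
        "block_dims": {b.name: b.dim for b in blocks},
        "n_obs": n,
    }

    master = np.random.SeedSequence(seed)
    for c, child in enumerate(master.spawn(chains)):
        rng = np.random.default_rng(child)
        # --- initialization (OLS-ish, jittered across chains)
        beta = np.linalg.lstsq(
            X + 0.0, y, rcond=None
        )[0] + rng.normal(0, 0.1 * sd_y, size=p)
        b_vals = [np.zeros((b.n_groups, b.dim)) for b in blocks]
        Sigmas = [np.eye(b.dim) * (0.1 * sd_y) ** 2 for b in blocks]
        resid0 = y - X @ beta
        sigma2 = max(float(np.var(resid0)), 1e-8) * rng.uniform(0.5, 1.5)
        nu = 10.0
        w = np.ones(n)
        y_aug = y.copy()

        def scale_shape_logpost(log_s2, log_nu2, e):
            """Marginal (w integrated out) conditional of (sigma^2, nu)."""
            s2 = np.exp(log_s2)
            nu_ = 2.0 + np.exp(log_nu2)
            ll = float(np.sum(stats.t.logpdf(e, df=nu_, scale=np.sqrt(s2))))
            lp = -(priors.var_a + 1.0) * log_s2 - priors.var_b / s2
            lp += stats.gamma.logpdf(nu_ - 2.0, priors.nu_shape,
                                     scale=priors.nu_scale)
            return ll + lp + log_s2 + log_nu2  # log-scale Jacobians

        step = np.array([0.1, 0.3])  # adaptive MH steps for (log s2, log nu-2)
        acc = np.zeros(2)
        tries = 0

        total = warmup + draws * thin
        for it in range(total):
            # contributions of each block to the linear predictor
            contrib = [
                np.einsum("nd,nd->n", b.Z, b_vals[g][b.index])
                for g, b in enumerate(blocks)
            ]
            mu = X @ beta + (np.sum(contrib, axis=0) if blocks else 0.0)

            # --- impute censored responses from the truncated normal
            if cens.any():
                sd_i = np.sqrt(sigma2 / w[cens])
                y_aug[cens] = _sample_truncated_normal_above(
                    mu[cens], sd_i, bound, rng
                )

            e = y_aug - mu
            if student:
                # --- (sigma^2, nu) jointly by marginal MH (weights
                # integrated out), which avoids the slow w coupling
                cur = np.array([np.log(sigma2), np.log(nu - 2.0)])
                lp_cur = scale_shape_logpost(cur[0], cur[1], e)
                for comp in (0, 1):
                    prop = cur.copy()
                    prop[comp] += step[comp] * rng.standard_normal()
                    lp_prop = scale_shape_logpost(prop[0], prop[1], e)
                    if np.log(rng.uniform()) < lp_prop - lp_cur:
                        cur, lp_cur = prop, lp_prop
                        acc[comp] += 1
                sigma2, nu = np.exp(cur[0]), 2.0 + np.exp(cur[1])
                tries += 1
                if it < warmup and tries % 25 == 0:  # adapt toward ~40% accept
                    step *= np.exp((acc / 25.0 - 0.4) * 0.5)
                    step = np.clip(step, 1e-3, 2.0)
                    acc[:] = 0
                # --- refresh Student-t mixture weights from the exact
                # conditional given the new (sigma, nu)
                rate = (nu + (e * e) / sigma2) / 2.0
                w = rng.gamma((nu + 1.0) / 2.0, 1.0 / rate)
            else:
                w = np.ones(n)
                nu = np.inf

            # --- fixed effects
            r = y_aug - (np.sum(contrib, axis=0) if blocks else 0.0)
            Xw = X * w[:, None]
            A = (X.T @ Xw) / sigma2 + fe_prec * np.eye(p)
            rhs = (Xw.T @ r) / sigma2
            cov = np.linalg.inv(A)
            beta = rng.multivariate_normal(cov @ rhs, cov, method="cholesky")

            # --- random effects per block
            for g, b in enumerate(blocks):
                r_g = y_aug - X @ beta
                for g2, b2 in enumerate(blocks):
                    if g2 != g:
                        r_g = r_g - contrib[g2]
                A_g, rhs_g = _group_crossprods(b.Z, b.index, w, r_g, b.n_groups)
                prec = A_g / sigma2 + np.linalg.inv(Sigmas[g])[None, :, :]
                cov_g = np.linalg.inv(prec)
                mean_g = np.einsum("gij,gj->gi", cov_g, rhs_g / sigma2)
                L = np.linalg.cholesky(cov_g)
                z = rng.standard_normal((b.n_groups, b.dim))
                b_vals[g] = mean_g + np.einsum("gij,gj->gi", L, z)

                # --- translation (recentering) move: shift the RE mean
                # into the matching FE columns; exact conjugate draw
                if b.fe_cols is not None and b.n_groups > 1:
                    cols = list(b.fe_cols)
                    Sig_inv = np.linalg.inv(Sigmas[g])
                    P = b.n_groups * Sig_inv + fe_prec * np.eye(b.dim)
                    Cm = np.linalg.inv(P)
                    bbar = b_vals[g].mean(axis=0)
                    mean_m = Cm @ (
                        b.n_groups * (Sig_inv @ bbar) - fe_prec * beta[cols]
                    )
                    m_shift = rng.multivariate_normal(mean_m, Cm,
                                                      method="cholesky")
                    b_vals[g] = b_vals[g] - m_shift
                    beta[cols] = beta[cols] + m_shift

                contrib[g] = np.einsum("nd,nd->n", b.Z, b_vals[g][b.index])

                # --- RE (co)variance
                S = b_vals[g].T @ b_vals[g]
                if b.dim == 1:
                    a_post = priors.var_a + b.n_groups / 2.0
                    b_post = priors.var_b + S[0, 0] / 2.0
                    Sigmas[g] = np.array([[b_post / rng.gamma(a_post)]])
                else:
                    df_post = b.dim + 1 + b.n_groups
                    scale_post = priors.iw_scale * np.eye(b.dim) + S
                    Sigmas[g] = stats.invwishart.rvs(
                        df=df_post, scale=scale_post, random_state=rng
                    )

            # --- nested reallocation moves: shift mass between a child
            # block's effects and its parent's (e.g. individual vs family
            # intercepts of a twin pair, which the likelihood confounds)
            for child_name, parent_name, c2p in (nestings or ()):
                gc = block_pos[child_name]
                gp = block_pos[parent_name]
                d = blocks[gc].dim
                Su_inv = np.linalg.inv(Sigmas[gc])
                Sv_inv = np.linalg.inv(Sigmas[gp])
                Gp = blocks[gp].n_groups
                n_k = np.bincount(c2p, minlength=Gp)
                sum_u = np.empty((Gp, d))
                for j in range(d):
                    sum_u[:, j] = np.bincount(
                        c2p, weights=b_vals[gc][:, j], minlength=Gp
                    )
                P = Sv_inv[None, :, :] + n_k[:, None, None] * Su_inv[None, :, :]
                rhs = sum_u @ Su_inv.T - b_vals[gp] @ Sv_inv.T
                Cm = np.linalg.inv(P)
                mean_m = np.einsum("gij,gj->gi", Cm, rhs)
                Lm = np.linalg.cholesky(Cm)
                z = rng.standard_normal((Gp, d))
                m_k = mean_m + np.einsum("gij,gj->gi", Lm, z)
                b_vals[gc] = b_vals[gc] - m_k[c2p]
                b_vals[gp] = b_vals[gp] + m_k
                contrib[gc] = np.einsum(
                    "nd,nd->n", blocks[gc].Z, b_vals[gc][blocks[gc].index]
                )
                contrib[gp] = np.einsum(
                    "nd,nd->n", blocks[gp].Z, b_vals[gp][blocks[gp].index]
                )

            # --- interweaving (ASIS) update of scalar RE SDs: re-draw tau
            # in the non-centered parameterization, where it is a
            # regression slope on the whitened effects; this unsticks
            # variance components near zero
            for g, b in enumerate(blocks):
                if b.dim != 1:
                    continue
                tau = np.sqrt(Sigmas[g][0, 0])
                if tau < 1e-12:
                    continue
                eta = b_vals[g][:, 0] / tau
                contrib_all = np.sum(contrib, axis=0)
                r = y_aug - X @ beta - (contrib_all - contrib[g])
                q = eta[b.index] * b.Z[:, 0]
                sqq = float(np.sum(w * q * q)) / sigma2
                sqr = float(np.sum(w * q * r)) / sigma2
                a_pr, b_pr = priors.var_a, priors.var_b

                def logf(t, sqq=sqq, sqr=sqr):
                    if t == 0.0:
                        return -np.inf
                    return (
                        -0.5 * sqq * t * t + sqr * t
                        - (2 * a_pr + 1) * np.log(abs(t))
                        - b_pr / (t * t)
                    )

                width = 2.0 / np.sqrt(sqq + 1.0 / (sd_y**2))
                t_new = _slice_sample_1d(logf, tau, width, rng)
                b_vals[g][:, 0] = t_new * eta
                Sigmas[g] = np.array([[t_new * t_new]])
                contrib[g] = q * t_new

            # --- residual variance (conjugate; Student-t case is handled
            # by the marginal MH step above)
            if not student:
                mu = X @ beta + (np.sum(contrib, axis=0) if blocks else 0.0)
                e = y_aug - mu
                a_post = priors.var_a + n / 2.0
                b_post = priors.var_b + float(np.sum(w * e * e)) / 2.0
                sigma2 = b_post / rng.gamma(a_post)

            # --- store
            if it >= warmup and (it - warmup) % thin == 0:
                s = (it - warmup) // thin
                out["beta"][c, s] = beta
                out["sigma"][c, s] = np.sqrt(sigma2)
                out["nu"][c, s] = nu
                for g, b in enumerate(blocks):
                    out["Sigma"][b.name][c, s] = Sigmas[g]
                    if b.store_groups:
                        out["groups"][b.name][c, s] = b_vals[g]
    return out
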