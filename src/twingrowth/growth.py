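"""Bayesian multilevel growth-curve models for the twin cohort.

Behavioral noise-blast durations have a four-level structure (trials within
measurement occasions within individuals within families); ROI contrast
scores have three levels (wave observations within individuals within
families).  Both are modeled with quadratic age trajectories, Student-t
residuals, and -- for behavior -- right-censoring at the response ceiling.

The behavioral linear predictor (contrast parameterization, the default) is

    mu = (gamma0 + occasion) + gamma1*a + gamma2*a^2
         + (beta0+u0+v0)*c + (beta1+u1+v1)*c*a + (beta2+u2+v2)*c*a^2

with ``a`` age centered at ``centering_age`` (years) and ``c`` the
negative-feedback indicator; u are individual-level and v family-level
random growth components.  A ``raw`` switch instead models negative-trial
durations alone with the growth components on the outcome itself, which is
also the neural parameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .gibbs import Priors, REBlock, sample_hierarchical
from .params import COMPONENTS, NEURAL_OUTCOMES

_POLY = ("intercept", "linear", "quadratic")


@dataclass
class GrowthModelSpec:
    """Model and sampler settings for one outcome."""

    outcome: str = "behavior"
    centering_age: Optional[float] = None  # None -> pooled mean age
    censor_bound: float = 3500.0  # ms, behavior only
    residual_family: str = "student_t"
    parameterization: str = "contrast"  # behavior: 'contrast' or 'raw'
    chains: int = 2
    warmup: int = 400
    draws: int = 500
    thin: int = 1
    seed: int = 0
    max_rhat: float = 1.01
    min_ess: float = 400.0
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self):
        if self.outcome not in ("behavior",) + NEURAL_OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.parameterization not in ("contrast", "raw"):
            raise ValueError("parameterization must be 'contrast' or 'raw'")


@dataclass
class PosteriorDraws:
    """MCMC draws for one fitted outcome.

    Arrays keep a leading chain dimension; ``flat_*`` helpers concatenate
    chains in draw order.
    """

    outcome: str
    kind: str  # 'growth' or 'intercept_only'
    fe_names: list[str]
    beta: np.ndarray  # (C, S, p)
    sigma: np.ndarray  # (C, S)
    nu: np.ndarray  # (C, S)
    Sigma: dict[str, np.ndarray]  # level -> (C, S, d, d)
    groups: dict[str, np.ndarray]  # level -> (C, S, G, d)
    group_labels: dict[str, np.ndarray]
    centering_age: float
    individual_family: Optional[dict[str, str]] = None
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    converged: bool = True
    contrast_slice: slice = field(default_factory=lambda: slice(0, 3))  # FE cols of beta0..beta2

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape((-1,) + arr.shape[2:])

    def flat_beta(self) -> np.ndarray:
        return self.flat(self.beta)

    def flat_contrast_fe(self) -> np.ndarray:
        """Growth-component FE draws (S, 3)."""
        return self.flat(self.beta)[:, self.contrast_slice]

    def re_sd(self, level: str) -> np.ndarray:
        """(S, d) random-effect SD draws at a level."""
        S = self.flat(self.Sigma[level])
        return np.sqrt(np.einsum("sii->si", S))

    def re_corr(self, level: str) -> np.ndarray:
        S = self.flat(self.Sigma[level])
        sd = np.sqrt(np.einsum("sii->si", S))
        return S / (sd[:, :, None] * sd[:, None, :])

    def save(self, path) -> None:
        """Write draws to ``<path>.npz`` plus ``<path>.json`` metadata."""
        import json
        from pathlib import Path

        path = Path(path)
        arrays = {"beta": self.beta, "sigma": self.sigma, "nu": self.nu}
        for lev, arr in self.Sigma.items():
            arrays[f"Sigma_{lev}"] = arr
        for lev, arr in self.groups.items():
            arrays[f"groups_{lev}"] = arr
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {
            "outcome": self.outcome,
            "kind": self.kind,
            "fe_names": self.fe_names,
            "centering_age": self.centering_age,
            "converged": bool(self.converged),
            "contrast_slice": [self.contrast_slice.start,
                               self.contrast_slice.stop],
            "group_labels": {k: np.asarray(v).tolist()
                             for k, v in self.group_labels.items()},
            "individual_family": self.individual_family,
            "diagnostics": self.diagnostics.to_dict(orient="records"),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        import json
        from pathlib import Path

        path = Path(path)
        with np.load(path.with_suffix(".npz")) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(path.with_suffix(".json").read_text())
        Sigma = {k[len("Sigma_"):]: v for k, v in arrays.items()
                 if k.startswith("Sigma_")}
        groups = {k[len("groups_"):]: v for k, v in arrays.items()
                  if k.startswith("groups_")}
        return cls(
            outcome=meta["outcome"],
            kind=meta["kind"],
            fe_names=meta["fe_names"],
            beta=arrays["beta"],
            sigma=arrays["sigma"],
            nu=arrays["nu"],
            Sigma=Sigma,
            groups=groups,
            group_labels={k: np.asarray(v)
                          for k, v in meta["group_labels"].items()},
            centering_age=meta["centering_age"],
            individual_family=meta["individual_family"],
            diagnostics=pd.DataFrame(meta["diagnostics"]),
            converged=meta["converged"],
            contrast_slice=slice(*meta["contrast_slice"]),
        )


def _diagnose(named: dict[str, np.ndarray], max_rhat: float, min_ess: float):
    """R-hat and bulk ESS per scalar parameter via arviz."""
    import arviz as az

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in named.items():
            if not np.all(np.isfinite(arr)):
                continue
            rhat = float(az.rhat(az.convert_to_dataset(arr))["x"].values)
            ess = float(az.ess(az.convert_to_dataset(arr))["x"].values)
            rows.append((name, rhat, ess))
    diag = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk"])
    single_chain = named and next(iter(named.values())).shape[0] < 2
    ok = bool(
        len(diag) == 0
        or (
            (single_chain or (diag["rhat"] <= max_rhat).all())
            and (diag["ess_bulk"] >= min_ess).all()
        )
    )
    return diag, ok


def _behavior_arrays(trials: pd.DataFrame, spec: GrowthModelSpec):
    df = trials[trials["condition"].isin(("negative", "neutral"))].copy()
    if spec.parameterization == "raw":
        df = df[df["condition"] == "negative"].copy()
    df = df.dropna(subset=["duration_ms", "age_years"])
    y = df["duration_ms"].to_numpy(dtype=float) / 1000.0
    cens = df["censored"].to_numpy(dtype=bool)
    center = (
        spec.centering_age
        if spec.centering_age is not None
        else float(df["age_years"].mean())
    )
    a = df["age_years"].to_numpy(dtype=float) - center
    poly = np.column_stack([np.ones_like(a), a, a * a])
    return df, y, cens, a, poly, center


def _index_block(values: pd.Series):
    labels, idx = np.unique(values.to_numpy(), return_inverse=True)
    return labels, idx


def _fit(y, X, blocks, cens, bound, spec: GrowthModelSpec, fe_names,
         kind, outcome, center, ind_fam=None, contrast_slice=slice(0, 3),
         nestings=None):
    raw = sample_hierarchical(
        y, X, blocks,
        censored=cens, bound=bound,
        family=spec.residual_family,
        chains=spec.chains, warmup=spec.warmup, draws=spec.draws,
        thin=spec.thin, seed=spec.seed, priors=spec.priors,
        nestings=nestings,
    )
    named = {fe_names[j]: raw["beta"][:, :, j] for j in range(len(fe_names))}
    named["sigma"] = raw["sigma"]
    if spec.residual_family == "student_t":
        named["nu"] = raw["nu"]
    for b in blocks:
        for j in range(b.dim):
            named[f"sd_{b.name}[{j}]"] = np.sqrt(
                raw["Sigma"][b.name][:, :, j, j]
            )
    diag, ok = _diagnose(named, spec.max_rhat, spec.min_ess)
    if not ok:
        warnings.warn(
            f"{outcome} {kind} fit failed convergence thresholds "
            f"(max R-hat {diag['rhat'].max():.3f}, "
            f"min ESS {diag['ess_bulk'].min():.0f})"
        )
    return PosteriorDraws(
        outcome=outcome,
        kind=kind,
        fe_names=list(fe_names),
        beta=raw["beta"],
        sigma=raw["sigma"],
        nu=raw["nu"],
        Sigma=raw["Sigma"],
        groups=raw["groups"],
        group_labels={b.name: b.labels for b in blocks},
        centering_age=center,
        individual_family=ind_fam,
        diagnostics=diag,
        converged=ok,
        contrast_slice=contrast_slice,
    )


def fit_growth(data: pd.DataFrame, spec: GrowthModelSpec) -> PosteriorDraws:
    """Fit the growth-curve model for one outcome.

    ``data`` is the trials table for ``behavior`` or the ROI table for a
    neural outcome.  Rows with missing outcome values drop out of the
    likelihood, which is ignorable under missing-at-random.
    """
    if spec.outcome == "behavior":
        df, y, cens, a, poly, center = _behavior_arrays(data, spec)
        occ_labels, occ_idx = _index_block(
            df["individual_id"].astype(str) + "@" + df["wave"].astype(str)
        )
        ind_labels, ind_idx = _index_block(df["individual_id"])
        fam_labels, fam_idx = _index_block(df["family_id"])
        if spec.parameterization == "contrast":
            c = (df["condition"] == "negative").to_numpy(dtype=float)
            X = np.column_stack([poly, poly * c[:, None]])
            fe_names = [f"gamma_{p}" for p in _POLY] + [f"beta_{p}" for p in _POLY]
            Z_growth = poly * c[:, None]
            cslice = slice(3, 6)
        else:
            X = poly
            fe_names = [f"beta_{p}" for p in _POLY]
            Z_growth = poly
            cslice = slice(0, 3)
        growth_cols = tuple(range(cslice.start, cslice.stop))
        blocks = [
            REBlock("occasion", np.ones((len(y), 1)), occ_idx, len(occ_labels),
                    labels=occ_labels, fe_cols=(0,)),
            REBlock("individual", Z_growth, ind_idx, len(ind_labels),
                    labels=ind_labels, store_groups=True, fe_cols=growth_cols),
            REBlock("family", Z_growth, fam_idx, len(fam_labels),
                    labels=fam_labels, store_groups=True, fe_cols=growth_cols),
        ]
        ind_fam = dict(
            df.groupby("individual_id")["family_id"].first().astype(str)
        )
        fam_pos = {lab: j for j, lab in enumerate(fam_labels)}
        c2p = np.array([fam_pos[ind_fam[l]] for l in ind_labels])
        bound = spec.censor_bound / 1000.0
        return _fit(y, X, blocks, cens, bound, spec, fe_names, "growth",
                    "behavior", center, ind_fam, cslice,
                    nestings=[("individual", "family", c2p)])

    df = data[data["roi"] == spec.outcome].dropna(subset=["contrast", "age_years"])
    y = df["contrast"].to_numpy(dtype=float)
    center = (
        spec.centering_age
        if spec.centering_age is not None
        else float(df["age_years"].mean())
    )
    a = df["age_years"].to_numpy(dtype=float) - center
    X = np.column_stack([np.ones_like(a), a, a * a])
    ind_labels, ind_idx = _index_block(df["individual_id"])
    fam_labels, fam_idx = _index_block(df["family_id"])
    blocks = [
        REBlock("individual", X, ind_idx, len(ind_labels),
                labels=ind_labels, store_groups=True, fe_cols=(0, 1, 2)),
        REBlock("family", X, fam_idx, len(fam_labels),
                labels=fam_labels, store_groups=True, fe_cols=(0, 1, 2)),
    ]
    ind_fam = dict(df.groupby("individual_id")["family_id"].first().astype(str))
    fam_pos = {lab: j for j, lab in enumerate(fam_labels)}
    c2p = np.array([fam_pos[ind_fam[l]] for l in ind_labels])
    fe_names = [f"beta_{p}" for p in _POLY]
    return _fit(y, X, blocks, None, None, spec, fe_names, "growth",
                spec.outcome, center, ind_fam, slice(0, 3),
                nestings=[("individual", "family", c2p)])


def fit_intercept_only(data: pd.DataFrame, spec: GrowthModelSpec) -> PosteriorDraws:
    """Variance-decomposition model: random intercepts at every level."""
    if spec.outcome == "behavior":
        df, y, cens, a, poly, center = _behavior_arrays(
            data, replace(spec, parameterization="contrast")
        )
        occ_labels, occ_idx = _index_block(
            df["individual_id"].astype(str) + "@" + df["wave"].astype(str)
        )
        ind_labels, ind_idx = _index_block(df["individual_id"])
        fam_labels, fam_idx = _index_block(df["family_id"])
        ones = np.ones((len(y), 1))
        blocks = [
            REBlock("occasion", ones, occ_idx, len(occ_labels),
                    labels=occ_labels, fe_cols=(0,)),
            REBlock("individual", ones, ind_idx, len(ind_labels),
                    labels=ind_labels, fe_cols=(0,)),
            REBlock("family", ones, fam_idx, len(fam_labels),
                    labels=fam_labels, fe_cols=(0,)),
        ]
        ind_pos = {lab: j for j, lab in enumerate(ind_labels)}
        fam_pos = {lab: j for j, lab in enumerate(fam_labels)}
        ind_of_occ = df.groupby(
            df["individual_id"].astype(str) + "@" + df["wave"].astype(str)
        )["individual_id"].first()
        fam_of_ind = df.groupby("individual_id")["family_id"].first()
        occ2ind = np.array([ind_pos[ind_of_occ[l]] for l in occ_labels])
        ind2fam = np.array([fam_pos[fam_of_ind[l]] for l in ind_labels])
        return _fit(y, ones, blocks, cens, spec.censor_bound / 1000.0, spec,
                    ["intercept"], "intercept_only", "behavior", center,
                    contrast_slice=slice(0, 1),
                    nestings=[("occasion", "individual", occ2ind),
                              ("individual", "family", ind2fam)])

    df = data[data["roi"] == spec.outcome].dropna(subset=["contrast"])
    y = df["contrast"].to_numpy(dtype=float)
    ind_labels, ind_idx = _index_block(df["individual_id"])
    fam_labels, fam_idx = _index_block(df["family_id"])
    ones = np.ones((len(y), 1))
    blocks = [
        REBlock("individual", ones, ind_idx, len(ind_labels),
                labels=ind_labels, fe_cols=(0,)),
        REBlock("family", ones, fam_idx, len(fam_labels),
                labels=fam_labels, fe_cols=(0,)),
    ]
    center = float(df["age_years"].mean()) if "age_years" in df else 0.0
    fam_pos = {lab: j for j, lab in enumerate(fam_labels)}
    fam_of_ind = df.groupby("individual_id")["family_id"].first()
    ind2fam = np.array([fam_pos[fam_of_ind[l]] for l in ind_labels])
    return _fit(y, ones, blocks, None, None, spec, ["intercept"],
                "intercept_only", spec.outcome, center,
                contrast_slice=slice(0, 1),
                nestings=[("individual", "family", ind2fam)])


def compute_icc(draws: PosteriorDraws, epsilon: float = 0.01) -> pd.DataFrame:
    """Intraclass correlations per grouping level from an intercept-only fit.

    Per draw, ICC_level = V_level / (sum of level variances + residual
    variance), with the Student-t residual variance sigma^2 * nu/(nu-2).
    The level shares plus the residual share sum to one by construction.
    """
    if draws.kind != "intercept_only":
        raise ValueError("ICCs are defined for intercept-only fits")
    nu = draws.flat(draws.nu)
    if np.any(nu[np.isfinite(nu)] <= 2):
        raise ValueError("draws contain nu <= 2; residual variance undefined")
    sigma = draws.flat(draws.sigma)
    t_factor = np.where(np.isfinite(nu), nu / (nu - 2.0), 1.0)
    v_resid = sigma**2 * t_factor
    levels = list(draws.Sigma)
    v_levels = {
        lev: draws.flat(draws.Sigma[lev])[:, 0, 0] for lev in levels
    }
    total = v_resid + sum(v_levels.values())
    rows = []
    for lev in levels + ["residual"]:
        share = (v_resid if lev == "residual" else v_levels[lev]) / total
        assert np.all((share >= 0) & (share <= 1))
        lo, hi = np.percentile(share, [2.5, 97.5])
        rows.append({
            "level": lev,
            "icc_mean": float(share.mean()),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "p_gt_epsilon": float((share > epsilon).mean()),
        })
    out = pd.DataFrame(rows)
    shares = np.column_stack(
        [v_levels[lev] for lev in levels] + [v_resid]
    ) / total[:, None]
    np.testing.assert_allclose(shares.sum(axis=1), 1.0, rtol=1e-10)
    return out


def summarize_growth(draws: PosteriorDraws) -> pd.DataFrame:
    """Equal-tailed 95% credible intervals for FEs and RE SDs."""
    rows = []

    def add(name, samples):
        lo, hi = np.percentile(samples, [2.5, 97.5])
        rows.append({
            "parameter": name,
            "mean": float(np.mean(samples)),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "excludes_zero": bool(lo > 0 or hi < 0),
        })

    beta = draws.flat_beta()
    for j, name in enumerate(draws.fe_names):
        add(f"FE {name}", beta[:, j])
    for level in draws.Sigma:
        sd = draws.re_sd(level)
        comps = _POLY[: sd.shape[1]] if sd.shape[1] > 1 else ("intercept",)
        for j, comp in enumerate(comps):
            add(f"SD(RE) {level} {comp}", sd[:, j])
    add("sigma", draws.flat(draws.sigma))
    nu = draws.flat(draws.nu)
    if np.all(np.isfinite(nu)):
        add("nu", nu)
    return pd.DataFrame(rows)


def predict_trajectory(
    draws: PosteriorDraws,
    ages: np.ndarray,
    n_curves: int = 100,
) -> dict:
    """Predicted mean trajectory and posterior uncertainty curves.

    The bold curve evaluates the posterior-mean growth-component FEs on the
    age grid; the uncertainty curves use evenly thinned posterior draws.
    For behavior (contrast parameterization) these are negative-vs-neutral
    contrast trajectories.
    """
    ages = np.asarray(ages, dtype=float)
    a = ages - draws.centering_age
    basis = np.column_stack([np.ones_like(a), a, a * a])
    fe = draws.flat_contrast_fe()
    mean_curve = basis @ fe.mean(axis=0)
    n_curves = min(n_curves, fe.shape[0])
    idx = np.linspace(0, fe.shape[0] - 1, n_curves).round().astype(int)
    curves = fe[idx] @ basis.T
    return {
        "ages": ages,
        "mean": mean_curve,
        "curves": curves,
        "centering_age": draws.centering_age,
    }


def extract_plausible_values(
    draws_by_outcome: dict[str, PosteriorDraws],
    m: int = 1000,
) -> pd.DataFrame:
    """Plausible values of individual-specific growth components.

    For thinned draw ``s`` and individual ``i`` in family ``k`` the
    component is ``beta_s + u_{s,ik} + v_{s,k}`` for each of intercept,
    linear and quadratic, per outcome.  The four outcome posteriors are
    fitted independently; sets are paired across outcomes by thinned draw
    index.  Individuals missing an outcome entirely receive missing values
    for that outcome's components.
    """
    rosters = []
    for out, d in draws_by_outcome.items():
        if d.n_draws < m:
            raise ValueError(
                f"{out}: requested m={m} plausible-value sets but only "
                f"{d.n_draws} draws are available; run longer chains"
            )
        if "individual" not in d.groups or "family" not in d.groups:
            raise ValueError(f"{out}: fit did not store group-level draws")
        rosters.append(set(d.group_labels["individual"]))
    individuals = sorted(set().union(*rosters))
    n_ind = len(individuals)
    frames = {"draw": np.repeat(np.arange(1, m + 1), n_ind),
              "individual_id": np.tile(np.array(individuals), m)}
    for out, d in draws_by_outcome.items():
        S = d.n_draws
        idx = np.linspace(0, S - 1, m).round().astype(int)
        fe = d.flat_contrast_fe()[idx]  # (m, 3)
        u = d.flat(d.groups["individual"])[idx]  # (m, G_i, d)
        v = d.flat(d.groups["family"])[idx]  # (m, G_f, d)
        ind_labels = list(d.group_labels["individual"])
        fam_labels = {lab: j for j, lab in enumerate(d.group_labels["family"])}
        pos = {lab: j for j, lab in enumerate(ind_labels)}
        vals = np.full((m, n_ind, 3), np.nan)
        for col, ind in enumerate(individuals):
            j = pos.get(ind)
            if j is None:
                continue
            k = fam_labels[d.individual_family[ind]]
            vals[:, col, :] = fe + u[:, j, :3] + v[:, k, :3]
        for comp_j, comp in enumerate(COMPONENTS):
            frames[f"{out}_{comp}"] = vals[:, :, comp_j].reshape(-1)
    pv = pd.DataFrame(frames)
    arr = pv.drop(columns=["draw", "individual_id"]).to_numpy()
    if np.isinf(arr).any():
        raise AssertionError("non-finite plausible values")
    return pv


def prior_predictive_durations(
    spec: GrowthModelSpec,
    sd_y: float = 1.0,
    n: int = 5000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Durations simulated from the priors alone (degenerate-prior guard).

    Draws fixed effects, residual scale and t degrees of freedom from the
    prior and generates censored durations (ms); a healthy prior spans the
    whole observable range [0, bound].
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    pri = spec.priors
    mu = rng.normal(0.0, pri.fe_scale * sd_y, size=n)
    sigma2 = pri.var_b / rng.gamma(pri.var_a, size=n)
    sigma = np.sqrt(np.minimum(sigma2, 1e6))
    nu = 2.0 + rng.gamma(pri.nu_shape, pri.nu_scale, size=n)
    y = mu + sigma * rng.standard_t(nu)
    y_ms = np.clip(y * 1000.0, 0.0, spec.censor_bound)
    return y_ms
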