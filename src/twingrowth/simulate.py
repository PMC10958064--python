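"""Seeded synthetic twin-cohort generator.

Produces trial-level noise-blast durations (three feedback conditions,
right-censored at the response ceiling, heavy-tailed Student-t residuals),
wave-level ROI contrast scores for three brain regions, and well-being
subscale scores at the final wave, with monotone missing-at-random dropout
whose rates match the published per-wave retention.

All randomness flows from ``CohortConfig.seed`` (or an explicit
``numpy.random.Generator``); identical seeds give byte-identical tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.optimize import brentq

from .params import (
    CONDITIONS,
    NEURAL_OUTCOMES,
    OUTCOMES,
    SUBSCALES,
    CohortConfig,
    TruthParams,
    WellbeingTruth,
    truth_to_json,
)

TRIAL_COLUMNS = [
    "family_id", "individual_id", "zygosity", "wave", "age_years",
    "trial_index", "condition", "duration_ms", "censored",
]
ROI_COLUMNS = ["family_id", "individual_id", "wave", "age_years", "roi", "contrast"]
MEMBERSHIP_COLUMNS = [
    "family_id", "individual_id", "zygosity",
    "present_w1", "present_w3", "present_w5",
    "age_w1", "age_w3", "age_w5", "wellbeing_present",
]

WAVES = (1, 3, 5)  # lab-visit waves of the cohort design


class Cohort(NamedTuple):
    """Tables produced by :func:`simulate_cohort`.

    ``components`` holds each individual's true growth components
    (fixed effect + individual RE + family RE), used when generating
    well-being outcomes with nonzero brain/behavior effects.
    """

    trials: pd.DataFrame
    roi: pd.DataFrame
    membership: pd.DataFrame
    components: pd.DataFrame


def _calibrate_logistic_intercept(z: np.ndarray, slope: float, target: float) -> float:
    """Intercept a such that mean(expit(a + slope*z)) == target."""
    if target >= 1.0:
        return np.inf

    def f(a):
        return expit(a + slope * z).mean() - target

    return brentq(f, -30.0, 30.0)


def simulate_cohort(
    config: CohortConfig,
    truth: Optional[TruthParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> Cohort:
    """Simulate a full twin cohort under the hierarchical growth model.

    Durations are generated in milliseconds on the task scale, censored at
    ``config.censor_bound`` (the ``censored`` flag is set iff the recorded
    duration equals the bound).  Twins share family-level random effects and
    visit ages; dropout is monotone and depends only on the observed wave-1
    mean duration (MAR).
    """
    truth = truth if truth is not None else TruthParams()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    n_fam = config.n_families
    fam_ids = np.array([f"F{k:04d}" for k in range(n_fam)])
    n_mz = int(round(config.prop_mz * n_fam))
    zyg_fam = np.array(["MZ"] * n_mz + ["DZ"] * (n_fam - n_mz))
    rng.shuffle(zyg_fam)

    # visit ages shared by twins: wave-1 uniform on its range, +2y +- 0.25y
    lo1, hi1 = config.wave_ages[0]
    ages = np.empty((n_fam, 3))
    ages[:, 0] = rng.uniform(lo1, hi1, size=n_fam)
    for w in (1, 2):
        ages[:, w] = ages[:, w - 1] + 2.0 + rng.uniform(-0.25, 0.25, size=n_fam)

    n_ind = 2 * n_fam
    ind_fam = np.repeat(np.arange(n_fam), 2)
    ind_ids = np.array([f"{fam_ids[k]}_{j + 1}" for k in range(n_fam) for j in (0, 1)])

    # random effects per outcome: family 3-vectors shared by twins,
    # individual 3-vectors (optionally extra-similar for MZ pairs)
    u_re: dict[str, np.ndarray] = {}
    v_re: dict[str, np.ndarray] = {}
    for outcome in OUTCOMES:
        t = truth[outcome]
        v = rng.multivariate_normal(np.zeros(3), t.cov_v(), size=n_fam)
        u = rng.multivariate_normal(np.zeros(3), t.cov_u(), size=n_ind)
        b = config.mz_similarity_boost
        if b > 0:
            shared = rng.multivariate_normal(np.zeros(3), t.cov_u(), size=n_fam)
            mz = zyg_fam[ind_fam] == "MZ"
            u[mz] = np.sqrt(1 - b) * u[mz] + np.sqrt(b) * shared[ind_fam][mz]
        u_re[outcome], v_re[outcome] = u, v

    beh = truth["behavior"]
    tau_w = float(beh.tau_w)
    occ_re = rng.normal(0.0, tau_w, size=(n_ind, 3))  # occasion intercepts
    u_base = rng.normal(0.0, beh.tau_u_base, size=n_ind)
    v_base = rng.normal(0.0, beh.tau_v_base, size=n_fam)

    a_c = ages - truth.centering_age  # (n_fam, 3) centered ages
    n_per_cond = config.trials_per_condition
    n_trials = n_per_cond * len(CONDITIONS)
    U_ms = config.censor_bound
    U_s = U_ms / 1000.0

    # simulate every individual's trials at every wave; dropout masks later
    trial_rows = []
    dur_all = np.empty((n_ind, 3, n_trials))
    cond_all = np.empty((n_ind, 3, n_trials), dtype=object)
    for i in range(n_ind):
        k = ind_fam[i]
        for w in range(3):
            a = a_c[k, w]
            poly = np.array([1.0, a, a * a])
            mu_neu = float(np.dot(beh.gamma, poly)) + occ_re[i, w] + u_base[i] + v_base[k]
            contrast = float(np.dot(beh.beta + u_re["behavior"][i] + v_re["behavior"][k], poly))
            conds = np.repeat(np.array(CONDITIONS, dtype=object), n_per_cond)
            rng.shuffle(conds)
            mu = np.where(conds == "negative", mu_neu + contrast, mu_neu)
            y = mu + beh.sigma * rng.standard_t(beh.nu, size=n_trials)
            dur_all[i, w] = np.maximum(y, 0.0)  # durations cannot be negative
            cond_all[i, w] = conds

    # MAR monotone dropout on standardized observed wave-1 mean duration
    present = np.zeros((n_ind, 3), dtype=bool)
    present[:, 0] = rng.random(n_ind) < config.retention[0]
    w1_mean = np.minimum(dur_all[:, 0, :], U_s).mean(axis=1)  # observed scale
    if n_ind > 0 and present[:, 0].any():
        z = (w1_mean - w1_mean[present[:, 0]].mean())
        sd = w1_mean[present[:, 0]].std()
        z = z / sd if sd > 0 else z * 0.0
        alive = present[:, 0]
        for w in (1, 2):
            target = config.retention[w] / config.retention[w - 1]
            if target >= 1.0:
                keep = np.ones(n_ind, dtype=bool)
            else:
                a0 = _calibrate_logistic_intercept(z[alive], config.dropout_slope, target)
                keep = rng.random(n_ind) < expit(a0 + config.dropout_slope * z)
            present[:, w] = alive & keep
            alive = present[:, w]

    for i in range(n_ind):
        k = ind_fam[i]
        for w in range(3):
            if not present[i, w]:
                continue
            y_ms = dur_all[i, w] * 1000.0
            cens = y_ms >= U_ms
            y_ms = np.minimum(y_ms, U_ms)
            for t_idx in range(n_trials):
                trial_rows.append((
                    fam_ids[k], ind_ids[i], zyg_fam[k], WAVES[w],
                    round(ages[k, w], 4), t_idx + 1, cond_all[i, w][t_idx],
                    y_ms[t_idx], bool(cens[t_idx]),
                ))
    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)

    # ROI contrast scores, with independent per-wave scan-completion thinning
    roi_rows = []
    for i in range(n_ind):
        k = ind_fam[i]
        for w in range(3):
            if not present[i, w] or rng.random() >= config.mri_completion[w]:
                continue
            a = a_c[k, w]
            poly = np.array([1.0, a, a * a])
            for roi in NEURAL_OUTCOMES:
                t = truth[roi]
                mu = float(np.dot(t.beta + u_re[roi][i] + v_re[roi][k], poly))
                val = mu + t.sigma * rng.standard_t(t.nu)
                roi_rows.append((fam_ids[k], ind_ids[i], WAVES[w],
                                 round(ages[k, w], 4), roi, val))
    roi = pd.DataFrame(roi_rows, columns=ROI_COLUMNS)

    wb_present = present[:, 2] & (rng.random(n_ind) < config.wellbeing_fraction)
    membership = pd.DataFrame({
        "family_id": fam_ids[ind_fam],
        "individual_id": ind_ids,
        "zygosity": zyg_fam[ind_fam],
        "present_w1": present[:, 0],
        "present_w3": present[:, 1],
        "present_w5": present[:, 2],
        "age_w1": np.round(ages[ind_fam, 0], 4),
        "age_w3": np.round(ages[ind_fam, 1], 4),
        "age_w5": np.round(ages[ind_fam, 2], 4),
        "wellbeing_present": wb_present,
    })

    comp_cols = {}
    for outcome in OUTCOMES:
        t = truth[outcome]
        total = t.beta + u_re[outcome] + v_re[outcome][ind_fam]
        for j, comp in enumerate(("intercept", "linear", "quadratic")):
            comp_cols[f"{outcome}_{comp}"] = total[:, j]
    components = pd.DataFrame({"individual_id": ind_ids, **comp_cols})

    return Cohort(trials, roi, membership, components)


def simulate_wellbeing(
    membership: pd.DataFrame,
    components: pd.DataFrame,
    truth: WellbeingTruth,
    coefficients: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Generate five subscale scores from a one-factor model.

    The latent factor is centered at zero with disturbance variance
    ``truth.psi``; optionally it is a linear function of the supplied true
    growth components (``coefficients``, one per component column), which
    supports power studies with real brain/behavior -> well-being effects.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    ids = membership.loc[membership["wellbeing_present"].astype(bool), "individual_id"]
    comp = components.set_index("individual_id").loc[ids]
    n = len(ids)
    factor = rng.normal(0.0, np.sqrt(truth.psi), size=n)
    if coefficients is not None:
        coefficients = np.asarray(coefficients, dtype=float)
        x = comp.to_numpy()
        if coefficients.shape != (x.shape[1],):
            raise ValueError(
                f"expected {x.shape[1]} coefficients, got {coefficients.shape}"
            )
        factor = factor + (x - x.mean(axis=0)) @ coefficients
    lam = np.asarray(truth.loadings)
    resid = rng.multivariate_normal(np.zeros(5), truth.residual_cov(), size=n)
    scores = np.asarray(truth.means) + factor[:, None] * lam + resid
    out = pd.DataFrame(scores, columns=list(SUBSCALES))
    out.insert(0, "individual_id", ids.to_numpy())
    return out.reset_index(drop=True)


def validate_cohort(trials: pd.DataFrame, censor_bound: float) -> None:
    """Schema validation; raises ValueError listing offending rows."""
    bad_cond = ~trials["condition"].isin(CONDITIONS)
    if bad_cond.any():
        raise ValueError(
            f"unknown condition labels at rows {list(trials.index[bad_cond][:10])}"
        )
    over = trials["duration_ms"] > censor_bound
    if over.any():
        raise ValueError(
            f"durations exceed censor bound at rows {list(trials.index[over][:10])}"
        )
    flag = trials["censored"].astype(bool)
    mismatch = flag & (trials["duration_ms"] != censor_bound)
    if mismatch.any():
        raise ValueError(
            "censored flag set but duration != bound at rows "
            f"{list(trials.index[mismatch][:10])}"
        )
    # monotone dropout: presence at a wave implies presence at earlier waves
    pres = trials.groupby(["individual_id", "wave"]).size().unstack(fill_value=0) > 0
    for w in pres.columns:
        earlier = [c for c in pres.columns if c < w]
        for e in earlier:
            bad = pres[w] & ~pres[e]
            if bad.any():
                raise ValueError(
                    f"non-monotone dropout: individuals {list(pres.index[bad][:10])} "
                    f"present at wave {w} but absent at wave {e}"
                )


def write_cohort(
    path: str | Path,
    cohort: Cohort,
    wellbeing: Optional[pd.DataFrame] = None,
    config: Optional[CohortConfig] = None,
    truth: Optional[TruthParams] = None,
    wellbeing_truth: Optional[WellbeingTruth] = None,
) -> Path:
    """Write the cohort CSVs (plus a truth.json echo when truth is given)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.trials.to_csv(path / "trials.csv", index=False)
    cohort.roi.to_csv(path / "roi.csv", index=False)
    cohort.membership.to_csv(path / "membership.csv", index=False)
    cohort.components.to_csv(path / "components.csv", index=False)
    if wellbeing is not None:
        wellbeing.to_csv(path / "wellbeing.csv", index=False)
    if config is not None and truth is not None:
        (path / "truth.json").write_text(truth_to_json(config, truth, wellbeing_truth))
    return path


def read_cohort(path: str | Path, censor_bound: Optional[float] = 3500.0) -> Cohort:
    """Read and validate a cohort written by :func:`write_cohort`."""
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv")
    if trials.empty:
        trials = pd.DataFrame(columns=TRIAL_COLUMNS)
    else:
        trials["censored"] = trials["censored"].astype(bool)
    roi = pd.read_csv(path / "roi.csv")
    if roi.empty:
        roi = pd.DataFrame(columns=ROI_COLUMNS)
    membership = pd.read_csv(path / "membership.csv")
    comp_file = path / "components.csv"
    components = pd.read_csv(comp_file) if comp_file.exists() else pd.DataFrame()
    if censor_bound is not None and len(trials):
        validate_cohort(trials, censor_bound)
    return Cohort(trials, roi, membership, components)
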