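"""End-to-end pipeline: simulate (or load) the cohort, fit the growth
models, decompose variance, extract plausible values, score well-being,
branch on the CFA, fit the per-draw saturated SEM and pool by Rubin's
rules, writing tables, figures and a manifest to a run directory.

All randomness derives from one master seed through named
``numpy.random.SeedSequence`` children, so a rerun with the same
configuration reproduces every numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .growth import (
    GrowthModelSpec,
    compute_icc,
    extract_plausible_values,
    fit_growth,
    fit_intercept_only,
    predict_trajectory,
    summarize_growth,
)
from .params import (
    OUTCOMES,
    SUBSCALES,
    CohortConfig,
    TruthParams,
    WellbeingTruth,
    _jsonable,
)
from .pooled import fit_sem_draw, pool_draw_fits, pooled_report
from .simulate import read_cohort, simulate_cohort, simulate_wellbeing, write_cohort
from .wellbeing import CfaThresholds, branch_on_fit, fit_one_factor_cfa

# stage names, in execution order
STAGES = ("simulate", "icc", "growth", "cfa", "sem")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    truth: TruthParams = field(default_factory=TruthParams)
    wellbeing_truth: WellbeingTruth = field(default_factory=WellbeingTruth)
    #: real-data mode: directory with trials.csv / roi.csv / wellbeing.csv
    data_dir: Optional[str] = None
    growth: GrowthModelSpec = field(default_factory=GrowthModelSpec)
    m: int = 1000
    n_trajectory_curves: int = 100
    cfa_thresholds: CfaThresholds = field(default_factory=CfaThresholds)
    alpha: float = 0.05
    icc_epsilon: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**raw.pop("cohort"))
        if "growth" in raw:
            kwargs["growth"] = GrowthModelSpec(**raw.pop("growth"))
        if "cfa_thresholds" in raw:
            kwargs["cfa_thresholds"] = CfaThresholds(**raw.pop("cfa_thresholds"))
        kwargs.update(raw)
        return cls(**kwargs)


def _stage_seed(master: int, stage: str, extra: str = "") -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master}:{stage}:{extra}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _outputs_exist(out: Path, names: list[str]) -> bool:
    return all((out / n).exists() for n in names)


def render_figures(trajectories: dict[str, dict], path: Path) -> Path:
    """Four-panel trajectory figure (behavior + three ROIs).

    Bold line: fixed-effect posterior-mean trajectory; gray lines: thinned
    posterior draws; vertical dotted red line: the centering age.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), constrained_layout=True)
    panels = "abcd"
    for ax, (outcome, tr), tag in zip(axes.ravel(), trajectories.items(), panels):
        for curve in tr["curves"]:
            ax.plot(tr["ages"], curve, color="0.7", lw=0.5, zorder=1)
        ax.plot(tr["ages"], tr["mean"], color="black", lw=2.2, zorder=2)
        ax.axvline(tr["centering_age"], color="red", ls=":", lw=1.2)
        ax.set_xlim(tr["ages"].min(), tr["ages"].max())
        label = "noise-blast contrast (s)" if outcome == "behavior" else "contrast (a.u.)"
        ax.set_xlabel("age (years)")
        ax.set_ylabel(label)
        ax.set_title(f"({tag}) {outcome}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute every stage; returns the run directory.

    With ``resume=True``, a stage whose outputs all exist is skipped, but
    once any stage re-runs every downstream stage re-runs too.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(config),
        "versions": _versions(),
        "stages": {},
    }
    dirty = False

    def begin(stage, outputs):
        nonlocal dirty
        if resume and not dirty and _outputs_exist(out, outputs):
            manifest["stages"][stage] = {"skipped": True}
            return False
        dirty = True
        return True

    def finish(stage, t0, outputs, **info):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "outputs": {n: _hash_file(out / n) for n in outputs},
            **info,
        }
        _write_manifest(out, manifest)

    # ---- stage: simulate (or point at real data)
    data_dir = out / "data"
    sim_outputs = [f"data/{n}" for n in
                   ("trials.csv", "roi.csv", "membership.csv",
                    "components.csv", "wellbeing.csv", "truth.json")]
    if config.data_dir is not None:
        data_dir = Path(config.data_dir)
        manifest["stages"]["simulate"] = {"skipped": True, "data_dir": str(data_dir)}
    elif begin("simulate", sim_outputs):
        t0 = time.time()
        rng = np.random.default_rng(_stage_seed(config.seed, "simulate"))
        cohort = simulate_cohort(config.cohort, config.truth, rng=rng)
        wb = simulate_wellbeing(
            cohort.membership, cohort.components, config.wellbeing_truth,
            rng=np.random.default_rng(_stage_seed(config.seed, "wellbeing")),
        )
        write_cohort(data_dir, cohort, wellbeing=wb, config=config.cohort,
                     truth=config.truth, wellbeing_truth=config.wellbeing_truth)
        finish("simulate", t0, sim_outputs)

    cohort = read_cohort(data_dir, censor_bound=config.cohort.censor_bound)
    wellbeing = pd.read_csv(data_dir / "wellbeing.csv")

    # ---- stage: intercept-only models and ICC table
    if begin("icc", ["icc.csv"]):
        t0 = time.time()
        tables = []
        for outcome in OUTCOMES:
            spec = dataclasses.replace(
                config.growth, outcome=outcome,
                seed=_stage_seed(config.seed, "icc", outcome),
            )
            data = cohort.trials if outcome == "behavior" else cohort.roi
            fit = fit_intercept_only(data, spec)
            icc = compute_icc(fit, epsilon=config.icc_epsilon)
            icc.insert(0, "outcome", outcome)
            icc["converged"] = fit.converged
            tables.append(icc)
        pd.concat(tables).to_csv(out / "icc.csv", index=False)
        finish("icc", t0, ["icc.csv"])

    # ---- stage: growth fits, summaries, plausible values, figures
    growth_outputs = ["growth_summary.csv", "plausible_values.csv",
                      "trajectories.png"]
    if begin("growth", growth_outputs):
        t0 = time.time()
        fits, summaries, trajectories = {}, [], {}
        for outcome in OUTCOMES:
            spec = dataclasses.replace(
                config.growth, outcome=outcome,
                seed=_stage_seed(config.seed, "growth", outcome),
            )
            data = cohort.trials if outcome == "behavior" else cohort.roi
            fit = fit_growth(data, spec)
            fits[outcome] = fit
            summ = summarize_growth(fit)
            summ.insert(0, "outcome", outcome)
            summ["converged"] = fit.converged
            summaries.append(summ)
            ages = (cohort.trials if outcome == "behavior" else cohort.roi)[
                "age_years"
            ]
            grid = np.linspace(ages.min(), ages.max(), 60)
            trajectories[outcome] = predict_trajectory(
                fit, grid, config.n_trajectory_curves
            )
        pd.concat(summaries).to_csv(out / "growth_summary.csv", index=False)
        pv = extract_plausible_values(fits, m=config.m)
        pv.to_csv(out / "plausible_values.csv", index=False)
        render_figures(trajectories, out / "trajectories.png")
        finish("growth", t0, growth_outputs,
               converged={o: bool(f.converged) for o, f in fits.items()})

    # ---- stage: well-being CFA and branching decision
    if begin("cfa", ["cfa_fit.json"]):
        t0 = time.time()
        cfa = fit_one_factor_cfa(wellbeing)
        decision = branch_on_fit(cfa, config.cfa_thresholds)
        payload = {
            "loadings": cfa.loadings.tolist(),
            "uniquenesses": cfa.uniquenesses.tolist(),
            "psi": cfa.psi,
            "statistic": cfa.statistic, "df": cfa.df, "p_value": cfa.p_value,
            "cfi": cfa.cfi, "tli": cfa.tli, "rmsea": cfa.rmsea,
            "n_obs": cfa.n_obs, "heywood": cfa.heywood,
            "decision": decision,
            "thresholds": _jsonable(config.cfa_thresholds),
            "parameters": cfa.se.to_dict(orient="records"),
        }
        (out / "cfa_fit.json").write_text(json.dumps(payload, indent=2))
        finish("cfa", t0, ["cfa_fit.json"], decision=decision)

    decision = json.loads((out / "cfa_fit.json").read_text())["decision"]

    # ---- stage: per-draw saturated SEM + Rubin pooling
    sem_outputs = ["aim2_covariances.csv", "aim3_regression.csv",
                   "pooling_diagnostics.json"]
    if begin("sem", sem_outputs):
        t0 = time.time()
        pv = pd.read_csv(out / "plausible_values.csv")
        if decision == "common_factor":
            from .wellbeing import regression_factor_scores

            cfa_info = json.loads((out / "cfa_fit.json").read_text())
            outcomes_df = regression_factor_scores(
                cfa_info["loadings"], cfa_info["uniquenesses"],
                cfa_info["psi"], wellbeing,
            )
        else:
            outcomes_df = wellbeing[["individual_id"] + list(SUBSCALES)]
        draws_idx = sorted(pv["draw"].unique())
        fits = []
        for s in draws_idx:
            fits.append(fit_sem_draw(
                pv[pv["draw"] == s].drop(columns=["draw"]),
                outcomes_df,
                draw_index=int(s),
            ))
        nu_com = fits[0].n_obs - 12 - 1
        pooled = pool_draw_fits(fits, nu_com=nu_com)
        cov_tab, reg_tab = pooled_report(pooled, alpha=config.alpha)
        cov_tab.to_csv(out / "aim2_covariances.csv", index=False)
        reg_tab.to_csv(out / "aim3_regression.csv", index=False)
        diag = {
            "m": len(fits),
            "n_complete": fits[0].n_obs,
            "nu_com": nu_com,
            "decision": decision,
            "gamma_quartiles": np.percentile(
                pooled["gamma"], [25, 50, 75]
            ).tolist(),
            "between_within_ratio_median": float(
                (pooled["between_var"] / pooled["within_var"]).median()
            ),
            "n_significant_covariances": int(cov_tab["significant"].sum()),
            "n_significant_coefficients": int(reg_tab["significant"].sum()),
        }
        (out / "pooling_diagnostics.json").write_text(json.dumps(diag, indent=2))
        finish("sem", t0, sem_outputs, decision=decision)

    _write_manifest(out, manifest)
    return out


def _versions() -> dict:
    import arviz
    import matplotlib
    import scipy

    from . import __version__

    return {
        "twingrowth": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "arviz": arviz.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
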