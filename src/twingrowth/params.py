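"""Configuration and generative-truth parameter containers.

The synthetic cohort emulates a longitudinal same-sex twin study with three
lab waves at individually varying ages, a trial-based aggression task
(noise-blast durations, right-censored at a response ceiling), wave-level
fMRI ROI contrast scores (negative > neutral feedback) for three regions,
and five social well-being subscale scores at a final wave.

Default truth values are the midpoints of the published 95% credible
intervals for the fixed effects and random-effect SDs of the growth
components; quantities the study does not report (neutral-baseline
trajectory, occasion noise, residual scales, t degrees of freedom) are set
so that the intercept-only variance decomposition and censoring rate look
like the published ones.  See docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

OUTCOMES = ("behavior", "AI", "MPFC", "DLPFC")
NEURAL_OUTCOMES = ("AI", "MPFC", "DLPFC")
CONDITIONS = ("negative", "neutral", "positive")
SUBSCALES = ("AWP", "WHO", "SC", "CF", "GS")
COMPONENTS = ("intercept", "linear", "quadratic")

#: age (years) at which growth components are anchored by default
DEFAULT_CENTERING_AGE = 9.75


def _as_corr(mat) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    if m.shape != (3, 3) or not np.allclose(m, m.T):
        raise ValueError("correlation matrix must be symmetric 3x3")
    return m


def check_correlation(name: str, mat: np.ndarray) -> np.ndarray:
    """Validate a correlation matrix; raise naming the offending matrix."""
    m = _as_corr(mat)
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError(f"{name} must have unit diagonal")
    eig = np.linalg.eigvalsh(m)
    if eig.min() < -1e-10:
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {eig.min():.3g})"
        )
    return m


@dataclass
class GrowthTruth:
    """Generative parameters for one outcome's growth-curve model.

    ``beta`` are the fixed-effect intercept / linear / quadratic growth
    components on centered age (years).  For the behavioral outcome they
    parameterize the negative-vs-neutral *contrast* trajectory on top of the
    neutral baseline ``gamma``; for neural outcomes they are the trajectory
    of the ROI contrast score itself.
    """

    beta: tuple[float, float, float]
    tau_u: tuple[float, float, float]  # individual-level RE SDs
    tau_v: tuple[float, float, float]  # family-level RE SDs
    sigma: float  # residual scale of the Student-t
    nu: float = 8.0  # t degrees of freedom
    corr_u: np.ndarray = field(default_factory=lambda: np.eye(3))
    corr_v: np.ndarray = field(default_factory=lambda: np.eye(3))
    # behavior only: neutral-baseline trajectory and occasion-level SD
    gamma: Optional[tuple[float, float, float]] = None
    tau_w: Optional[float] = None
    # behavior only: condition-independent baseline intercept SDs
    # (overall response propensity of an individual / a family)
    tau_u_base: float = 0.0
    tau_v_base: float = 0.0

    def __post_init__(self):
        self.corr_u = check_correlation("corr_u", self.corr_u)
        self.corr_v = check_correlation("corr_v", self.corr_v)
        if min(self.tau_u) < 0 or min(self.tau_v) < 0 or self.sigma < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.nu <= 2:
            raise ValueError("t degrees of freedom must exceed 2")

    def cov_u(self) -> np.ndarray:
        d = np.diag(self.tau_u)
        return d @ self.corr_u @ d

    def cov_v(self) -> np.ndarray:
        d = np.diag(self.tau_v)
        return d @ self.corr_v @ d


def _default_outcomes() -> dict[str, GrowthTruth]:
    corr_ai = np.eye(3)
    corr_ai[0, 1] = corr_ai[1, 0] = -0.3  # intercept-linear coupling
    corr_mpfc = np.eye(3)
    corr_mpfc[0, 2] = corr_mpfc[2, 0] = -0.3  # intercept-quadratic coupling
    return {
        # behavior in seconds; contrast trajectory over a neutral baseline
        "behavior": GrowthTruth(
            beta=(1.40, -0.015, -0.045),
            tau_u=(0.225, 0.055, 0.015),
            tau_v=(0.29, 0.085, 0.025),
            sigma=0.70,
            nu=8.0,
            gamma=(1.50, -0.05, -0.01),
            tau_w=0.54,
        ),
        "AI": GrowthTruth(
            beta=(0.725, -0.155, 0.06),
            tau_u=(0.515, 0.345, 0.085),
            tau_v=(0.41, 0.18, 0.07),
            sigma=3.5,
            nu=8.0,
            corr_u=corr_ai,
        ),
        "MPFC": GrowthTruth(
            beta=(0.86, -0.035, 0.06),
            tau_u=(0.70, 0.285, 0.115),
            tau_v=(0.875, 0.155, 0.135),
            sigma=4.3,
            nu=8.0,
            corr_u=corr_mpfc,
        ),
        "DLPFC": GrowthTruth(
            beta=(-0.37, -0.015, 0.045),
            tau_u=(0.495, 0.275, 0.085),
            tau_v=(0.425, 0.22, 0.08),
            sigma=4.0,
            nu=8.0,
        ),
    }


@dataclass
class TruthParams:
    """Generative truth for all four outcomes."""

    outcomes: dict[str, GrowthTruth] = field(default_factory=_default_outcomes)
    centering_age: float = DEFAULT_CENTERING_AGE

    def __post_init__(self):
        missing = set(OUTCOMES) - set(self.outcomes)
        if missing:
            raise ValueError(f"missing truth for outcomes: {sorted(missing)}")
        beh = self.outcomes["behavior"]
        if beh.gamma is None or beh.tau_w is None:
            raise ValueError("behavior truth requires gamma and tau_w")

    def __getitem__(self, outcome: str) -> GrowthTruth:
        return self.outcomes[outcome]


@dataclass
class WellbeingTruth:
    """One-factor measurement model for the five well-being subscales.

    The first loading is fixed to 1 (marker scaling); ``psi`` is the
    common-factor variance; ``misfit`` optionally adds residual covariances
    among named subscale pairs, which makes a one-factor CFA misfit.
    """

    loadings: tuple[float, ...] = (1.0, 0.996, 0.766, 0.628, 1.161)
    uniquenesses: tuple[float, ...] = (0.051, 0.019, 0.299, 0.281, 0.275)
    psi: float = 0.141
    means: tuple[float, ...] = (3.0, 3.1, 2.9, 3.1, 3.0)
    misfit: Optional[dict[tuple[str, str], float]] = None

    def __post_init__(self):
        if len(self.loadings) != 5 or len(self.uniquenesses) != 5 or len(self.means) != 5:
            raise ValueError("exactly 5 subscales are required")
        if self.loadings[0] != 1.0:
            raise ValueError("first loading is the marker and must equal 1")
        if min(self.uniquenesses) < 0 or self.psi <= 0:
            raise ValueError("uniquenesses must be >= 0 and psi > 0")
        if np.linalg.eigvalsh(self.residual_cov()).min() < -1e-12:
            raise ValueError("residual covariance (with misfit) is not positive semi-definite")
        if np.linalg.eigvalsh(self.implied_cov()).min() < -1e-12:
            raise ValueError("implied covariance is not positive semi-definite")

    def residual_cov(self) -> np.ndarray:
        theta = np.diag(np.asarray(self.uniquenesses, dtype=float))
        if self.misfit:
            idx = {s: i for i, s in enumerate(SUBSCALES)}
            for (a, b), val in self.misfit.items():
                i, j = idx[a], idx[b]
                theta[i, j] = theta[j, i] = val
        return theta

    def implied_cov(self) -> np.ndarray:
        lam = np.asarray(self.loadings, dtype=float)
        return self.psi * np.outer(lam, lam) + self.residual_cov()


@dataclass
class CohortConfig:
    """Design of the simulated twin cohort.

    Defaults mirror the source cohort: 256 same-sex twin pairs (512
    children), 55% monozygotic, three lab waves with the published age
    ranges and retention, 20 trials per feedback condition per wave, and a
    3500 ms response ceiling.
    """

    n_families: int = 256
    prop_mz: float = 0.55
    wave_ages: tuple[tuple[float, float], ...] = (
        (7.02, 9.68),
        (8.97, 11.67),
        (11.15, 14.11),
    )
    retention: tuple[float, ...] = (1.0, 456 / 512, 336 / 512)
    trials_per_condition: int = 20
    censor_bound: float = 3500.0  # ms
    seed: int = 0
    #: fraction of retained participants with a usable scan, per wave
    mri_completion: tuple[float, ...] = (485 / 512, 408 / 456, 236 / 336)
    #: fraction of wave-3 (last lab wave) participants with well-being data
    wellbeing_fraction: float = 294 / 336
    #: slope of the logistic MAR dropout on standardized wave-1 mean duration
    dropout_slope: float = 0.5
    #: optional extra twin similarity for MZ pairs (0 = zygosity inert)
    mz_similarity_boost: float = 0.0

    def __post_init__(self):
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if not 0 <= self.prop_mz <= 1:
            raise ValueError("prop_mz must be in [0, 1]")
        if len(self.wave_ages) != 3 or len(self.retention) != 3:
            raise ValueError("three waves are required")
        for (lo, hi) in self.wave_ages:
            if not lo < hi:
                raise ValueError("each wave age range must have min < max")
        los = [lo for lo, _ in self.wave_ages]
        if not (los[0] < los[1] < los[2]):
            raise ValueError("age ranges must increase across waves")
        r = self.retention
        if not all(0 < x <= 1 for x in r) or not (r[0] >= r[1] >= r[2]):
            raise ValueError("retention must be in (0,1] and non-increasing")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.censor_bound <= 0:
            raise ValueError("censor_bound must be > 0")
        if not 0 <= self.mz_similarity_boost < 1:
            raise ValueError("mz_similarity_boost must be in [0, 1)")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def truth_to_json(config: CohortConfig, truth: TruthParams,
                  wellbeing: Optional[WellbeingTruth] = None) -> str:
    """Serialize all generating parameters for the truth.json echo."""
    payload = {"config": _jsonable(config), "truth": _jsonable(truth)}
    if wellbeing is not None:
        payload["wellbeing"] = _jsonable(wellbeing)
    return json.dumps(payload, indent=2)
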