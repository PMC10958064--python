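import numpy as np
import pandas as pd
import pytest

from twingrowth import (
    CohortConfig,
    TruthParams,
    compute_icc,
    extract_plausible_values,
    fit_growth,
    fit_intercept_only,
    predict_trajectory,
    simulate_cohort,
    summarize_growth,
)
from twingrowth.growth import GrowthModelSpec, PosteriorDraws
from twingrowth.params import OUTCOMES, GrowthTruth


def _make_draws(beta, sigma=1.0, nu=8.0, sigmas=None, groups=None,
                labels=None, kind="growth", fe_names=None, ind_fam=None):
    """Hand-built PosteriorDraws: beta is (S, p); one chain."""
    beta = np.asarray(beta, dtype=float)
    S, p = beta.shape
    sigmas = sigmas or {}
    return PosteriorDraws(
        outcome="behavior",
        kind=kind,
        fe_names=fe_names or [f"b{j}" for j in range(p)],
        beta=beta[None],
        sigma=np.full((1, S), sigma),
        nu=np.full((1, S), nu),
        Sigma={k: np.asarray(v)[None] for k, v in sigmas.items()},
        groups={k: np.asarray(v)[None] for k, v in (groups or {}).items()},
        group_labels=labels or {},
        centering_age=9.75,
        individual_family=ind_fam,
        contrast_slice=slice(0, 3),
    )


class TestFitGrowth:
    def test_noiseless_recovery(self):
        """With RE SDs ~0, tiny residual and no censoring, the posterior
        concentrates on the generating fixed effects."""
        beh = GrowthTruth(beta=(1.2, 0.1, -0.03), tau_u=(0, 0, 0),
                          tau_v=(0, 0, 0), sigma=0.02, nu=50.0,
                          gamma=(1.5, -0.05, 0.0), tau_w=0.0)
        truth = TruthParams(outcomes={**TruthParams().outcomes,
                                      "behavior": beh})
        cfg = CohortConfig(n_families=15, trials_per_condition=5, seed=11,
                           retention=(1.0, 1.0, 1.0))
        cohort = simulate_cohort(cfg, truth)
        spec = GrowthModelSpec(outcome="behavior", centering_age=9.75,
                               chains=2, warmup=200, draws=250, seed=1)
        fit = fit_growth(cohort.trials, spec)
        fe = fit.flat_contrast_fe()
        for j, true in enumerate((1.2, 0.1, -0.03)):
            mean, sd = fe[:, j].mean(), fe[:, j].std()
            assert abs(mean - true) < max(3 * sd, 0.01)
        for level in ("individual", "family"):
            assert fit.re_sd(level).mean(axis=0).max() < 0.05

    def test_student_t_and_gaussian_agree_on_gaussian_data(self):
        """On Gaussian data the Student-t fit matches a Gaussian-residual
        fit's fixed-effect posterior means within Monte-Carlo error."""
        beh = GrowthTruth(beta=(1.0, 0.0, 0.0), tau_u=(0.1, 0, 0),
                          tau_v=(0.1, 0, 0), sigma=0.5, nu=500.0,
                          gamma=(1.5, 0.0, 0.0), tau_w=0.3)
        truth = TruthParams(outcomes={**TruthParams().outcomes,
                                      "behavior": beh})
        cfg = CohortConfig(n_families=25, trials_per_condition=6, seed=12,
                           retention=(1.0, 1.0, 1.0), censor_bound=1e9)
        cohort = simulate_cohort(cfg, truth)
        means = {}
        for family in ("student_t", "gaussian"):
            spec = GrowthModelSpec(outcome="behavior", centering_age=9.75,
                                   residual_family=family, censor_bound=1e9,
                                   chains=2, warmup=200, draws=300, seed=2)
            fit = fit_growth(cohort.trials, spec)
            means[family] = fit.flat_contrast_fe().mean(axis=0)
        np.testing.assert_allclose(means["student_t"], means["gaussian"],
                                   atol=0.05)

    def test_neural_fit_recovers_intercept(self, small_cohort, default_truth):
        _, cohort = small_cohort
        spec = GrowthModelSpec(outcome="AI", centering_age=9.75, chains=2,
                               warmup=200, draws=250, seed=3)
        fit = fit_growth(cohort.roi, spec)
        fe = fit.flat_contrast_fe()
        true_b0 = default_truth["AI"].beta[0]
        assert abs(fe[:, 0].mean() - true_b0) < 4 * fe[:, 0].std() + 0.2


class TestInterceptOnly:
    def test_constant_data_gives_zero_variances(self, small_cohort):
        _, cohort = small_cohort
        t = cohort.trials.copy()
        t["duration_ms"] = 1000.0
        t["censored"] = False
        spec = GrowthModelSpec(outcome="behavior", chains=1, warmup=150,
                               draws=150, seed=4)
        fit = fit_intercept_only(t, spec)
        # on the seconds scale of the data (~1.0) these are all ~zero
        assert fit.flat(fit.sigma).mean() < 0.01
        for level in ("occasion", "individual", "family"):
            assert fit.re_sd(level).mean() < 0.01

    def test_single_family_runs_and_is_flagged(self, default_truth):
        """With one family the family variance is unidentified; the fit
        still returns, with diagnostics computed."""
        cfg = CohortConfig(n_families=1, trials_per_condition=5, seed=13,
                           retention=(1.0, 1.0, 1.0))
        cohort = simulate_cohort(cfg, default_truth)
        spec = GrowthModelSpec(outcome="behavior", chains=2, warmup=100,
                               draws=100, seed=5)
        with pytest.warns(UserWarning):
            fit = fit_intercept_only(cohort.trials, spec)
        assert not fit.converged
        assert np.isfinite(fit.re_sd("family")).all()


class TestIcc:
    def test_all_variance_at_family_level(self):
        d = _make_draws(np.ones((10, 1)), sigma=1e-9, nu=8.0,
                        sigmas={"occasion": np.zeros((10, 1, 1)),
                                "individual": np.zeros((10, 1, 1)),
                                "family": np.ones((10, 1, 1))},
                        kind="intercept_only")
        icc = compute_icc(d).set_index("level")
        assert icc.loc["family", "icc_mean"] > 0.999
        assert icc.loc["individual", "icc_mean"] < 1e-6

    def test_equal_shares_give_quarter_each(self):
        nu, v = 8.0, 0.25
        sigma = np.sqrt(v * (nu - 2) / nu)
        d = _make_draws(np.ones((10, 1)), sigma=sigma, nu=nu,
                        sigmas={k: np.full((10, 1, 1), v)
                                for k in ("occasion", "individual", "family")},
                        kind="intercept_only")
        icc = compute_icc(d)
        np.testing.assert_allclose(icc["icc_mean"], 0.25, atol=1e-12)

    def test_growth_fit_rejected(self):
        d = _make_draws(np.ones((5, 3)))
        with pytest.raises(ValueError, match="intercept-only"):
            compute_icc(d)


class TestSummaries:
    def test_constant_draws_give_point_interval(self):
        d = _make_draws(np.full((100, 1), 3.25), kind="intercept_only",
                        sigmas={"individual": np.full((100, 1, 1), 0.04)})
        tab = summarize_growth(d).set_index("parameter")
        row = tab.loc["FE b0"]
        assert row["ci_low"] == row["ci_high"] == 3.25
        sd_row = tab.loc["SD(RE) individual intercept"]
        assert sd_row["ci_low"] >= 0.0

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(0)
        d = _make_draws(rng.standard_normal((100_000, 1)))
        tab = summarize_growth(d).set_index("parameter")
        row = tab.loc["FE b0"]
        assert abs(row["ci_low"] + 1.96) < 0.04
        assert abs(row["ci_high"] - 1.96) < 0.04
        assert not row["excludes_zero"]


class TestTrajectory:
    def test_centering_age_returns_intercept(self):
        d = _make_draws(np.tile([1.0, 0.2, -0.1], (50, 1)))
        tr = predict_trajectory(d, np.array([9.75]))
        assert np.isclose(tr["mean"][0], 1.0)

    def test_vertex_closed_form(self):
        d = _make_draws(np.tile([1.0, 0.2, -0.1], (50, 1)))
        ages = np.linspace(7, 14, 701)
        tr = predict_trajectory(d, ages)
        peak_age = ages[np.argmax(tr["mean"])]
        assert abs(peak_age - (9.75 + 1.0)) < 0.02
        assert abs(tr["mean"].max() - 1.1) < 1e-4

    def test_negative_quadratic_mass_makes_all_curves_concave(self):
        rng = np.random.default_rng(1)
        beta = np.column_stack([
            rng.normal(1, 0.1, 200), rng.normal(0, 0.1, 200),
            -np.abs(rng.normal(0.05, 0.01, 200)),
        ])
        d = _make_draws(beta)
        tr = predict_trajectory(d, np.linspace(7, 13, 25), n_curves=200)
        second_diff = np.diff(tr["curves"], n=2, axis=1)
        assert (second_diff < 1e-12).all()


class TestPlausibleValues:
    def _fits(self, S, G_ind=4, G_fam=2, zero_re=True, rng=None):
        rng = rng or np.random.default_rng(0)
        fits = {}
        ind_labels = np.array([f"F{k}_{j}" for k in range(G_fam)
                               for j in (1, 2)])
        fam_labels = np.array([f"F{k}" for k in range(G_fam)])
        ind_fam = {f"F{k}_{j}": f"F{k}" for k in range(G_fam) for j in (1, 2)}
        for out in OUTCOMES:
            beta = rng.normal(size=(S, 3))
            u = (np.zeros((S, G_ind, 3)) if zero_re
                 else rng.normal(size=(S, G_ind, 3)))
            v = (np.zeros((S, G_fam, 3)) if zero_re
                 else rng.normal(size=(S, G_fam, 3)))
            fits[out] = _make_draws(
                beta, groups={"individual": u, "family": v},
                labels={"individual": ind_labels, "family": fam_labels},
                ind_fam=ind_fam,
            )
        return fits

    def test_zero_res_reduce_to_fixed_effects(self):
        fits = self._fits(S=20)
        pv = extract_plausible_values(fits, m=20)
        fe = fits["behavior"].flat_contrast_fe()
        for s in range(1, 21):
            sub = pv[pv["draw"] == s]
            np.testing.assert_allclose(sub["behavior_intercept"], fe[s - 1, 0])
            np.testing.assert_allclose(sub["behavior_quadratic"], fe[s - 1, 2])

    def test_shape_and_columns(self):
        fits = self._fits(S=30, zero_re=False)
        pv = extract_plausible_values(fits, m=10)
        assert len(pv) == 10 * 4  # m x individuals
        value_cols = [c for c in pv.columns
                      if c not in ("draw", "individual_id")]
        assert len(value_cols) == 12
        assert np.isfinite(pv[value_cols].to_numpy()).all()

    def test_component_identity(self):
        """PV = beta + u + v, row by row."""
        fits = self._fits(S=5, zero_re=False)
        pv = extract_plausible_values(fits, m=5)
        d = fits["MPFC"]
        fe = d.flat_contrast_fe()
        u = d.flat(d.groups["individual"])
        v = d.flat(d.groups["family"])
        row = pv[(pv["draw"] == 3) & (pv["individual_id"] == "F1_2")]
        expected = fe[2] + u[2, 3] + v[2, 1]
        np.testing.assert_allclose(
            row[["MPFC_intercept", "MPFC_linear", "MPFC_quadratic"]]
            .to_numpy()[0],
            expected,
        )

    def test_m_exceeding_draws_raises(self):
        fits = self._fits(S=5)
        with pytest.raises(ValueError, match="longer chains"):
            extract_plausible_values(fits, m=50)


class TestPersistence:
    def test_draws_round_trip(self, tmp_path, small_cohort):
        _, cohort = small_cohort
        spec = GrowthModelSpec(outcome="AI", chains=1, warmup=50, draws=60,
                               seed=9, min_ess=0, max_rhat=10.0)
        fit = fit_growth(cohort.roi, spec)
        fit.save(tmp_path / "ai_fit")
        back = PosteriorDraws.load(tmp_path / "ai_fit")
        np.testing.assert_array_equal(fit.beta, back.beta)
        np.testing.assert_array_equal(fit.groups["family"],
                                      back.groups["family"])
        assert back.fe_names == fit.fe_names
        assert back.centering_age == fit.centering_age
        assert (back.group_labels["individual"]
                == fit.group_labels["individual"]).all()


class TestPriorPredictive:
    def test_prior_durations_span_observable_range(self):
        from twingrowth.growth import prior_predictive_durations

        spec = GrowthModelSpec(outcome="behavior")
        y = prior_predictive_durations(spec, sd_y=1.0, n=20_000,
                                       rng=np.random.default_rng(3))
        # mass beyond both edges (clipped to the atoms) and in between:
        # the prior excludes no part of the observable range
        assert y.min() == 0.0 and y.max() == spec.censor_bound
        assert 0.0 < (y == 0.0).mean() < 1.0
        assert 0.0 < (y == spec.censor_bound).mean() < 1.0
        assert ((y > 0) & (y < spec.censor_bound)).any()
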