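import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twingrowth import (
    CohortConfig,
    TruthParams,
    WellbeingTruth,
    read_cohort,
    simulate_cohort,
    simulate_wellbeing,
    validate_cohort,
    write_cohort,
)
from twingrowth.params import SUBSCALES, GrowthTruth, check_correlation


def _truth_with_behavior(**kw):
    base = TruthParams()
    beh = GrowthTruth(**{**dict(
        beta=(1.4, -0.015, -0.045), tau_u=(0.2, 0.05, 0.01),
        tau_v=(0.3, 0.08, 0.02), sigma=0.7, nu=8.0,
        gamma=(1.5, -0.05, -0.01), tau_w=0.5,
    ), **kw})
    return TruthParams(outcomes={**base.outcomes, "behavior": beh})


class TestSimulateCohort:
    def test_trial_counts_per_wave(self, small_cohort):
        """Full retention gives trials_per_condition rows per condition per
        retained individual per wave."""
        cfg = CohortConfig(n_families=3, trials_per_condition=20, seed=0,
                           retention=(1.0, 1.0, 1.0))
        cohort = simulate_cohort(cfg)
        per_ind = cohort.trials.groupby("individual_id").size()
        assert (per_ind == 180).all()
        per_cell = cohort.trials.groupby(
            ["individual_id", "wave", "condition"]
        ).size()
        assert (per_cell == 20).all()
        per_wave = cohort.trials.groupby(["individual_id", "wave"]).size()
        assert (per_wave == 60).all()

    def test_degenerate_noise_reproduces_fixed_effects(self):
        """With all RE SDs zero and vanishing residual, every duration
        equals the fixed-effect mean at that age/condition."""
        truth = _truth_with_behavior(
            tau_u=(0, 0, 0), tau_v=(0, 0, 0), sigma=1e-12, tau_w=0.0,
            gamma=(1.5, 0.0, 0.0), beta=(1.0, 0.1, -0.02),
        )
        cfg = CohortConfig(n_families=4, trials_per_condition=3, seed=2,
                           retention=(1.0, 1.0, 1.0))
        cohort = simulate_cohort(cfg, truth)
        t = cohort.trials
        a = t["age_years"] - truth.centering_age
        mu = 1.5 + np.where(
            t["condition"] == "negative", 1.0 + 0.1 * a - 0.02 * a**2, 0.0
        )
        # ages in the table are rounded to 4 decimals, hence the tolerance
        np.testing.assert_allclose(t["duration_ms"] / 1000.0, mu, atol=1e-3)

    def test_censored_fraction_matches_t_survival(self):
        """Observed censoring per cell tracks the Student-t tail probability;
        with the mean at the bound the fraction is ~1/2."""
        from .oracles import t_tail_by_quadrature

        # negative-trial mean = gamma0 + beta0 = 3.5 s = the bound
        truth = _truth_with_behavior(
            beta=(2.0, 0, 0), gamma=(1.5, 0, 0), tau_u=(0, 0, 0),
            tau_v=(0, 0, 0), tau_w=0.0, sigma=0.7, nu=8.0,
        )
        cfg = CohortConfig(n_families=120, trials_per_condition=20, seed=3,
                           retention=(1.0, 1.0, 1.0))
        cohort = simulate_cohort(cfg, truth)
        neg = cohort.trials.query("condition == 'negative'")
        frac = neg["censored"].mean()
        n = len(neg)
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)
        # a cell away from the bound: neutral trials, tail by quadrature
        neu = cohort.trials.query("condition == 'neutral'")
        expected = t_tail_by_quadrature(3.5, 1.5, 0.7, 8.0)
        se = np.sqrt(expected * (1 - expected) / len(neu))
        assert abs(neu["censored"].mean() - expected) < 4 * max(se, 1e-4)

    def test_residual_kurtosis_increases_with_heavier_tails(self):
        """Excess kurtosis of uncensored residuals is positive at nu=5 and
        near zero at nu=1e6."""
        kurts = {}
        for nu in (5.0, 1e6):
            truth = _truth_with_behavior(
                tau_u=(0, 0, 0), tau_v=(0, 0, 0), tau_w=0.0, nu=nu,
                gamma=(10.0, 0, 0), beta=(0.0, 0, 0), sigma=0.7,
            )
            cfg = CohortConfig(n_families=150, trials_per_condition=20,
                               seed=4, retention=(1.0, 1.0, 1.0),
                               censor_bound=1e9)
            cohort = simulate_cohort(cfg, truth)
            kurts[nu] = stats.kurtosis(cohort.trials["duration_ms"])
        assert kurts[5.0] > 0.5
        assert abs(kurts[1e6]) < 0.2

    @pytest.mark.parametrize("tau_vs", [(0.0, 0.3, 0.6)])
    def test_within_family_correlation_monotone_in_family_sd(self, tau_vs):
        """Twin-twin correlation of mean durations is nondecreasing in the
        family-level SD, all else fixed."""
        cors = []
        for tau_v in tau_vs:
            truth = _truth_with_behavior(
                tau_v=(tau_v, 0, 0), tau_u=(0.1, 0, 0), tau_w=0.2, sigma=0.7,
            )
            cfg = CohortConfig(n_families=250, trials_per_condition=10,
                               seed=5, retention=(1.0, 1.0, 1.0),
                               censor_bound=1e9)
            cohort = simulate_cohort(cfg, truth)
            neg = cohort.trials.query("condition == 'negative'")
            m = neg.groupby(["family_id", "individual_id"])[
                "duration_ms"
            ].mean().reset_index()
            m["twin"] = m.groupby("family_id").cumcount()
            wide = m.pivot(index="family_id", columns="twin",
                           values="duration_ms")
            cors.append(wide[0].corr(wide[1]))
        assert cors[0] < cors[1] < cors[2]

    def test_retention_and_monotone_dropout(self, default_truth):
        cfg = CohortConfig(n_families=250, trials_per_condition=2, seed=6)
        cohort = simulate_cohort(cfg, default_truth)
        n0 = 2 * cfg.n_families
        for w, wave in enumerate((1, 3, 5)):
            n_w = cohort.trials.query("wave == @wave")["individual_id"].nunique()
            target = cfg.retention[w]
            se = np.sqrt(target * (1 - target) / n0)
            assert abs(n_w / n0 - target) < 4 * max(se, 0.01)
        validate_cohort(cohort.trials, cfg.censor_bound)  # monotone holds

    def test_identical_seed_identical_output(self, default_truth):
        cfg = CohortConfig(n_families=10, trials_per_condition=3, seed=7)
        a = simulate_cohort(cfg, default_truth)
        b = simulate_cohort(cfg, default_truth)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_bad_correlation_matrix_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99],
                        [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="corr_u"):
            GrowthTruth(beta=(0, 0, 0), tau_u=(1, 1, 1), tau_v=(1, 1, 1),
                        sigma=1.0, corr_u=bad)
        with pytest.raises(ValueError, match="positive semi-definite"):
            check_correlation("corr_v", bad)


class TestWellbeing:
    def _frames(self, n):
        membership = pd.DataFrame({
            "individual_id": [f"i{j}" for j in range(n)],
            "wellbeing_present": True,
        })
        comp = pd.DataFrame({"individual_id": membership["individual_id"]})
        for c in range(12):
            comp[f"x{c}"] = 0.0
        return membership, comp

    def test_sample_covariance_converges_to_model_implied(self):
        truth = WellbeingTruth()
        membership, comp = self._frames(40000)
        wb = simulate_wellbeing(membership, comp, truth,
                                rng=np.random.default_rng(8))
        S = np.cov(wb[list(SUBSCALES)].to_numpy(), rowvar=False)
        np.testing.assert_allclose(S, truth.implied_cov(), atol=0.012)

    def test_zero_uniqueness_gives_perfect_correlations(self):
        truth = WellbeingTruth(uniquenesses=(0.0,) * 5)
        membership, comp = self._frames(500)
        wb = simulate_wellbeing(membership, comp, truth,
                                rng=np.random.default_rng(9))
        R = np.corrcoef(wb[list(SUBSCALES)].to_numpy(), rowvar=False)
        np.testing.assert_allclose(np.abs(R), 1.0, atol=1e-10)

    def test_wrong_coefficient_count_rejected(self):
        membership, comp = self._frames(50)
        with pytest.raises(ValueError, match="coefficients"):
            simulate_wellbeing(membership, comp, WellbeingTruth(),
                               coefficients=np.ones(3))

    def test_misfit_requires_positive_definite_residuals(self):
        with pytest.raises(ValueError, match="positive"):
            WellbeingTruth(misfit={("AWP", "WHO"): 0.5})


class TestIO:
    def test_round_trip(self, small_cohort, tmp_path):
        cfg, cohort = small_cohort
        wb = simulate_wellbeing(cohort.membership, cohort.components,
                                WellbeingTruth(),
                                rng=np.random.default_rng(1))
        write_cohort(tmp_path / "c", cohort, wellbeing=wb, config=cfg,
                     truth=TruthParams())
        back = read_cohort(tmp_path / "c", censor_bound=cfg.censor_bound)
        pd.testing.assert_frame_equal(cohort.trials, back.trials)
        pd.testing.assert_frame_equal(cohort.roi, back.roi)
        assert (tmp_path / "c" / "truth.json").exists()

    def test_empty_cohort_round_trip(self, tmp_path):
        cfg = CohortConfig(n_families=0, seed=0)
        cohort = simulate_cohort(cfg)
        write_cohort(tmp_path / "e", cohort)
        back = read_cohort(tmp_path / "e")
        assert back.trials.empty and back.roi.empty
        assert list(back.trials.columns) == list(cohort.trials.columns)

    def test_duration_above_bound_rejected(self, small_cohort):
        _, cohort = small_cohort
        bad = cohort.trials.copy()
        bad.loc[bad.index[0], "duration_ms"] = 3600.0
        with pytest.raises(ValueError, match="exceed"):
            validate_cohort(bad, 3500.0)

    def test_unknown_condition_rejected(self, small_cohort):
        _, cohort = small_cohort
        bad = cohort.trials.copy()
        bad.loc[bad.index[5], "condition"] = "ambiguous"
        with pytest.raises(ValueError, match="condition"):
            validate_cohort(bad, 3500.0)

    def test_non_monotone_dropout_rejected(self, small_cohort):
        _, cohort = small_cohort
        t = cohort.trials
        ind = t["individual_id"].iloc[0]
        bad = t[~((t["individual_id"] == ind) & (t["wave"] == 1))]
        if (bad.query("individual_id == @ind")["wave"] > 1).any():
            with pytest.raises(ValueError, match="monotone"):
                validate_cohort(bad, 3500.0)
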