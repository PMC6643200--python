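"""Measurement-error model: numerics, fitting, posterior draws."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import dietqual as dq
from dietqual.me_model import (IdentifiabilityError, MODEL_COLUMNS, bvn_cdf,
                               component_amounts, posterior_moments)
from test_synthetic import no_effect_config, quiet_components


class TestBvnCdf:
    def test_matches_scipy_oracle(self):
        grid = [-1.5, -0.3, 0.0, 0.4, 2.0]
        for rho in (-0.6, 0.0, 0.35, 0.9):
            for h in grid:
                for k in grid:
                    want = multivariate_normal(
                        mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([h, k])
                    assert bvn_cdf(h, k, rho) == pytest.approx(
                        want, abs=5e-7), (h, k, rho)


class TestComponentAmounts:
    def test_ratio_and_empty_calories_derived(self):
        rec = pd.DataFrame({
            "energy": [1000.0], "pufa_g": [8.0], "mufa_g": [12.0],
            "sfa_g": [10.0], "solid_fat_kcal": [100.0],
            "added_sugar_kcal": [50.0], "alcohol_g": [20.0],
            **{c: [1.0] for c in MODEL_COLUMNS
               if c not in ("fatty_acids", "empty_calories", "energy")},
        })
        amounts = component_amounts(rec)
        assert amounts.loc[0, "fatty_acids"] == pytest.approx(2.0)
        # 100 + 50 + 7 kcal/g * (20 - 13) g excess alcohol
        assert amounts.loc[0, "empty_calories"] == pytest.approx(199.0)
        assert amounts.loc[0, "energy"] == 1000.0


class TestPosteriorMoments:
    def test_shrinkage_between_zero_and_recall_mean(self):
        # 1-component model: posterior mean lies between the prior mean (0)
        # and the person's mean residual, closer to it when recalls agree
        Sb = np.array([[1.0]])
        Se = np.array([[1.0]])
        resid = np.array([[2.0], [1.0]])  # two recalls, one person
        means, covs, grp = posterior_moments(resid, np.array([0, 0]), Sb, Se)
        rbar = 1.5
        assert 0.0 < means[0, 0] < rbar
        # conjugate closed form: (n/sigma2) / (n/sigma2 + 1/tau2) * rbar
        assert means[0, 0] == pytest.approx(2 / 3 * rbar, rel=1e-6)
        assert covs[grp[0], 0, 0] == pytest.approx(1 / 3, rel=1e-6)

    def test_single_recall_shrinks_harder_than_two(self):
        Sb = np.array([[1.0]])
        Se = np.array([[1.0]])
        means2, _, _ = posterior_moments(np.array([[1.0], [1.0]]),
                                         np.array([0, 0]), Sb, Se)
        means1, _, _ = posterior_moments(np.array([[1.0]]),
                                         np.array([0]), Sb, Se)
        assert means1[0, 0] < means2[0, 0]

    def test_missing_components_use_observed_subset(self):
        Sb = np.eye(2)
        Se = np.eye(2)
        resid = np.array([[1.0, np.nan], [1.0, 0.5]])
        means, _, _ = posterior_moments(resid, np.array([0, 0]), Sb, Se)
        assert means[0, 0] == pytest.approx(2 / 3, rel=1e-6)
        assert means[0, 1] == pytest.approx(0.25, rel=1e-6)


class TestFit:
    def test_requires_two_recall_participants(self, small_cohort):
        recalls = dq.generate_recalls(small_cohort)
        only_first = recalls[recalls["sequence"] == 1]
        with pytest.raises(IdentifiabilityError):
            dq.fit(only_first, small_cohort.covariates)

    def test_rejects_more_than_two_recalls(self, small_cohort):
        recalls = dq.generate_recalls(small_cohort)
        tripled = pd.concat([recalls, recalls[recalls["sequence"] == 1]])
        with pytest.raises(ValueError, match="more than two"):
            dq.fit(tripled, small_cohort.covariates)

    def test_detects_configured_episodic_components(self, small_cohort,
                                                    small_model):
        assert set(small_model.diagnostics["episodic_components"]) == set(
            small_cohort.config.episodic)

    def test_fixed_effects_recovered_within_sampling_error(self, small_cohort,
                                                           small_model):
        cfg = small_cohort.config
        for comp in ("energy", "total_vegetables", "sodium"):
            k = MODEL_COLUMNS.index(comp)
            scale = small_model.transforms[comp].scale
            for term, true_eff in [
                    ("weekend", cfg.effects["weekend"]),
                    ("usual_more", cfg.effects["usual_more"]),
                    ("seq2", cfg.effects["seq2"])]:
                want = true_eff * cfg.components[comp].responsiveness / scale
                got = small_model.beta.loc[term, comp]
                se = small_model.beta_se.loc[term, comp]
                assert abs(got - want) < 4 * se, (comp, term)

    def test_null_weekend_coefficient_ci_covers_zero(self):
        # nominal 95% CIs on a null effect should cover 0 in >=90% of runs
        covered = 0
        reps = 50
        for r in range(reps):
            cfg = dq.CohortConfig(
                n=300, seed=3000 + r, episodic={},
                effects=dict(dq.synthetic.DEFAULT_EFFECTS, weekend=0.0))
            cohort = dq.generate_cohort(cfg)
            model = dq.fit(dq.generate_recalls(cohort), cohort.covariates)
            b = model.beta.loc["weekend", "energy"]
            se = model.beta_se.loc["weekend", "energy"]
            covered += abs(b) <= 1.96 * se
        assert covered >= 0.9 * reps

    def test_degenerate_cohort_gives_null_covariances(self):
        cfg = no_effect_config(n=40, seed=2, components=quiet_components(),
                               episodic={})
        cohort = dq.generate_cohort(cfg)
        model = dq.fit(dq.generate_recalls(cohort), cohort.covariates)
        assert np.abs(model.Sigma_b).max() < 1e-6
        assert np.abs(model.Sigma_e).max() < 1e-6


class TestDrawUsual:
    def test_draw_count_and_nonnegativity(self, small_cohort, small_recalls,
                                          small_model):
        draws = dq.draw_usual(small_model, small_recalls,
                              small_cohort.covariates, M=7, seed=5)
        assert len(draws) == 7 * len(small_cohort.covariates)
        assert (draws.groupby("participant_id").size() == 7).all()
        for comp in MODEL_COLUMNS:
            assert (draws[comp] >= 0).all()

    def test_deterministic_under_seed(self, small_cohort, small_recalls,
                                      small_model):
        a = dq.draw_usual(small_model, small_recalls,
                          small_cohort.covariates, M=3, seed=11)
        b = dq.draw_usual(small_model, small_recalls,
                          small_cohort.covariates, M=3, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_draw_count_rejected(self, small_cohort, small_recalls,
                                         small_model):
        with pytest.raises(ValueError):
            dq.draw_usual(small_model, small_recalls,
                          small_cohort.covariates, M=0)

    def test_zero_variance_model_gives_identical_draws(self):
        cfg = no_effect_config(n=40, seed=2, components=quiet_components(),
                               episodic={})
        cohort = dq.generate_cohort(cfg)
        recalls = dq.generate_recalls(cohort)
        model = dq.fit(recalls, cohort.covariates)
        draws = dq.draw_usual(model, recalls, cohort.covariates, M=5, seed=0)
        rel_spread = draws.groupby("participant_id")["energy"].agg(
            lambda s: (s.max() - s.min()) / s.mean())
        assert (rel_spread < 1e-4).all()

    def test_usual_draws_less_dispersed_than_single_recalls(
            self, small_cohort, small_recalls, small_model):
        # the correction removes within-person noise, so usual intakes are
        # tighter across people than raw one-day amounts
        draws = dq.draw_usual(small_model, small_recalls,
                              small_cohort.covariates, M=20, seed=1)
        day1 = small_recalls[small_recalls["sequence"] == 1]
        for comp in ("energy", "total_fruit", "sodium"):
            assert draws[comp].var() < day1[comp].var()

    def test_json_round_trip_preserves_draws(self, tmp_path, small_cohort,
                                             small_recalls, small_model):
        path = tmp_path / "model.json"
        small_model.to_json(str(path))
        reloaded = dq.FittedMEModel.from_json(str(path))
        a = dq.draw_usual(small_model, small_recalls,
                          small_cohort.covariates, M=3, seed=2)
        b = dq.draw_usual(reloaded, small_recalls,
                          small_cohort.covariates, M=3, seed=2)
        pd.testing.assert_frame_equal(a, b, atol=1e-10, check_exact=False)
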