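"""Survey-weighted regression: outcome construction, WLS, backward selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import dietqual as dq
from dietqual import regression as reg
from dietqual.regression import (RegressionSpec, backward_select,
                                 build_design, fit_wls, person_hei)


def iid_design_for(data, seed=None, weight=None):
    n = len(data)
    w = np.ones(n) if weight is None else weight
    return pd.DataFrame({"id": data.get("participant_id", np.arange(n)),
                         "stratum": 0, "psu": np.arange(n), "weight": w})


class TestPersonHei:
    def test_identical_recalls_score_like_either(self, small_recalls,
                                                 standards):
        one = small_recalls[(small_recalls["participant_id"] == 1)
                            & (small_recalls["sequence"] == 1)]
        doubled = pd.concat([one, one.assign(sequence=2)])
        hei = person_hei(doubled, standards)
        single = dq.score_frame(one, standards)
        assert hei["score_total"].iloc[0] == pytest.approx(
            single["score_total"].iloc[0])

    def test_average_then_score_uses_averaged_density(self, standards):
        # energies 1000/3000, fruit 0/1.6 cup: averaged profile is
        # 0.8 cup at 2000 kcal = 0.4 cup/1000 kcal, NOT the mean of the
        # per-recall densities (0 and 0.533)
        base = {c: 0.0 for c in dq.COMPONENT_IDS
                if c not in ("fatty_acids", "empty_calories")}
        recalls = pd.DataFrame([
            {"participant_id": 1, "sequence": 1, **base, "total_fruit": 0.0,
             "energy": 1000.0, "pufa_g": 5, "mufa_g": 5, "sfa_g": 10,
             "solid_fat_kcal": 0, "added_sugar_kcal": 0, "alcohol_g": 0},
            {"participant_id": 1, "sequence": 2, **base, "total_fruit": 1.6,
             "energy": 3000.0, "pufa_g": 5, "mufa_g": 5, "sfa_g": 10,
             "solid_fat_kcal": 0, "added_sugar_kcal": 0, "alcohol_g": 0},
        ])
        hei = person_hei(recalls, standards)
        want = 5.0 * (0.4 / 0.8)
        assert hei["score_total"].iloc[0] - person_hei(
            recalls.assign(total_fruit=0.0), standards
        )["score_total"].iloc[0] == pytest.approx(want)

    def test_single_recall_participant_uses_that_recall(self, small_recalls,
                                                        standards):
        one = small_recalls[(small_recalls["participant_id"] == 2)
                            & (small_recalls["sequence"] == 1)]
        hei = person_hei(one, standards)
        single = dq.score_frame(one, standards)
        assert hei["score_total"].iloc[0] == pytest.approx(
            single["score_total"].iloc[0])

    def test_no_recalls_rejected(self, small_recalls):
        with pytest.raises(ValueError):
            person_hei(small_recalls.iloc[:0])


class TestFitWls:
    def test_reduces_to_ols_on_iid_design(self):
        rng = np.random.default_rng(0)
        n = 200
        data = pd.DataFrame({"age": rng.uniform(20, 70, n),
                             "sex": rng.choice(["male", "female"], n)})
        y = 10 + 0.1 * data["age"] + rng.normal(0, 2, n)
        X, cols, blocks = build_design(data, ["age", "sex"])
        res = fit_wls(y, X, iid_design_for(data), cols, blocks)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.table["estimate"], ols.params,
                                   rtol=1e-10)

    def test_recovers_seeded_age_and_sex_effects(self):
        cohort = dq.generate_cohort(dq.CohortConfig(n=3000, seed=14))
        data = cohort.covariates.copy()
        rng = np.random.default_rng(99)
        female = (data["sex"] == "female").to_numpy(float)
        y = 44.0 + 0.20 * data["age"] + 2.72 * female + rng.normal(0, 8, 3000)
        X, cols, blocks = build_design(data, ["age", "sex"])
        design = cohort.design.copy()
        res = fit_wls(y.to_numpy(), X, design, cols, blocks)
        t = res.table
        assert abs(t.loc["age", "estimate"] - 0.20) < 2 * t.loc["age", "se"]
        assert abs(t.loc["sex[female]", "estimate"] - 2.72) < \
            2 * t.loc["sex[female]", "se"]
        assert t.loc["intercept", "ci_low"] < 44.0 < \
            t.loc["intercept", "ci_high"]

    def test_duplicate_column_raises_naming_alias(self):
        rng = np.random.default_rng(1)
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        X = np.column_stack([X, X[:, 1]])  # duplicate
        with pytest.raises(ValueError, match="aliased.*dup"):
            fit_wls(rng.normal(size=n), X,
                    iid_design_for(pd.DataFrame(index=range(n))),
                    ["intercept", "x", "dup"])

    def test_weighted_r_squared_in_unit_interval(self, small_cohort):
        data = small_cohort.covariates
        rng = np.random.default_rng(3)
        y = 1.0 + rng.normal(size=len(data))
        X, cols, blocks = build_design(data, ["age"])
        res = fit_wls(y, X, small_cohort.design, cols, blocks)
        assert 0.0 <= res.r_squared <= 1.0


class TestBackwardSelect:
    def make_data(self, n, seed, effects=True):
        cohort = dq.generate_cohort(dq.CohortConfig(n=n, seed=seed))
        data = cohort.covariates.copy()
        rng = np.random.default_rng(seed + 1)
        female = (data["sex"] == "female").to_numpy(float)
        y = 44.0 + rng.normal(0, 8, n)
        if effects:
            y = y + 0.20 * data["age"].to_numpy() + 2.72 * female
        data["score_total"] = y
        design = cohort.design.set_index("id").loc[
            data["id"]].reset_index()
        return data, design

    def test_forced_only_spec_is_noop(self):
        data, design = self.make_data(500, 31)
        spec = RegressionSpec(candidates=["field_center", "heritage"])
        res = backward_select(spec, data, design)
        assert res.dropped == []
        assert set(res.selected) == {"field_center", "heritage"}

    def test_strong_effects_survive_forced_terms_always_kept(self):
        for seed in range(41, 51):
            data, design = self.make_data(800, seed)
            spec = RegressionSpec(candidates=[
                "age", "sex", "smoking", "field_center", "heritage"])
            res = backward_select(spec, data, design)
            assert {"age", "sex", "field_center", "heritage"} <= set(
                res.selected), seed

    def test_audit_trail_consistent_with_stay_level(self):
        data, design = self.make_data(800, 60)
        spec = RegressionSpec(candidates=[
            "age", "sex", "smoking", "activity", "income", "diabetes",
            "field_center", "heritage"])
        res = backward_select(spec, data, design)
        for term, p in res.dropped:
            assert p > spec.alpha_stay
            assert term not in res.selected
        for term, p in res.term_pvalues.items():
            if term not in spec.forced:
                assert p <= spec.alpha_stay

    def test_forced_must_be_candidates(self):
        with pytest.raises(ValueError):
            RegressionSpec(candidates=["age"])
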