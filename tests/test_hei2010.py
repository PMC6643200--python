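"""HEI-2010 scoring: densities, component scores, profiles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietqual.hei2010 as hei
from dietqual.hei2010 import (COMPONENT_IDS, IntakeProfile,
                              InvalidProfileError, MissingRatioError,
                              compute_density, empty_calorie_share,
                              fatty_acid_ratio, score_component, score_frame,
                              score_profile)


def adequacy_amounts(standards, energy=2000.0, factor=1.0):
    """Amounts putting each adequacy component at factor x its max standard."""
    return {
        c: s.density_at_max * factor * energy / 1000.0
        for c, s in standards.items()
        if s.direction == "adequacy" and c != "fatty_acids"
    }


def perfect_profile(standards, energy=2000.0):
    """Every component exactly at its maximum-score standard."""
    amounts = adequacy_amounts(standards, energy)
    amounts["refined_grains"] = 1.8 * energy / 1000.0
    amounts["sodium"] = 1.1 * energy / 1000.0
    amounts["fatty_acids"] = 2.5
    return IntakeProfile(energy=energy, amounts=amounts,
                         solid_fat_kcal=0.19 * energy)


class TestDensity:
    @pytest.mark.parametrize("amount,energy,expected", [
        (1.6, 2000.0, 0.8),    # exactly the total-fruit max standard
        (0.0, 1800.0, 0.0),
        (3.3, 1000.0, 3.3),
    ])
    def test_amount_per_1000_kcal(self, amount, energy, expected):
        assert compute_density(amount, energy) == pytest.approx(expected)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(InvalidProfileError):
            compute_density(1.0, 0.0)
        with pytest.raises(InvalidProfileError):
            compute_density(-1.0, 2000.0)

    def test_fatty_acid_ratio_edge_cases(self):
        assert fatty_acid_ratio(10.0, 15.0, 10.0) == pytest.approx(2.5)
        with pytest.warns(UserWarning):
            assert np.isposinf(fatty_acid_ratio(5.0, 5.0, 0.0))
        with pytest.raises(MissingRatioError):
            fatty_acid_ratio(0.0, 0.0, 0.0)


class TestComponentScore:
    def test_sodium_at_max_standard_earns_full_points(self, standards):
        assert score_component(1.1, standards["sodium"]) == pytest.approx(10.0)

    def test_adequacy_zero_density_scores_zero(self, standards):
        for cid in ("total_fruit", "whole_grains", "dairy"):
            assert score_component(0.0, standards[cid]) == 0.0

    def test_sodium_interpolation(self, standards):
        # independent linear oracle: (2.0 - 1.55) / (2.0 - 1.1) * 10
        assert score_component(1.55, standards["sodium"]) == pytest.approx(5.0)

    def test_matches_piecewise_linear_oracle_on_grid(self, standards):
        def oracle(d, s):
            # independently coded: sort anchors, clamp, interpolate
            lo, hi = sorted([s.density_at_zero, s.density_at_max])
            if s.direction == "adequacy" or s.direction == "ratio":
                if d <= lo:
                    return 0.0
                if d >= hi:
                    return float(s.max_points)
                return s.max_points * (d - lo) / (hi - lo)
            if d >= hi:
                return 0.0
            if d <= lo:
                return float(s.max_points)
            return s.max_points * (hi - d) / (hi - lo)

        for cid in COMPONENT_IDS:
            s = standards[cid]
            grid = np.linspace(0, 2.5 * max(s.density_at_zero,
                                            s.density_at_max), 41)
            got = score_component(grid, s)
            want = [oracle(d, s) for d in grid]
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_negative_density_rejected(self, standards):
        with pytest.raises(ValueError):
            score_component(-0.1, standards["sodium"])


class TestEmptyCalories:
    def test_solid_fat_plus_sugar_share(self):
        p = IntakeProfile(energy=2000.0, amounts={}, solid_fat_kcal=200.0,
                          added_sugar_kcal=180.0)
        assert empty_calorie_share(p) == pytest.approx(19.0)

    def test_all_zero(self):
        assert empty_calorie_share(
            IntakeProfile(energy=2000.0, amounts={})) == 0.0

    def test_alcohol_counts_only_above_threshold(self):
        # 26 g at 1000 kcal: 13 g excess * 7 kcal/g = 91 kcal = 9.1%
        p = IntakeProfile(energy=1000.0, amounts={}, alcohol_g=26.0)
        assert empty_calorie_share(p) == pytest.approx(9.1)


class TestProfileScoring:
    def test_perfect_adherence_scores_100(self, standards):
        score = score_profile(perfect_profile(standards), standards)
        assert score.total == pytest.approx(100.0)
        for cid in COMPONENT_IDS:
            assert score.component_scores[cid] == pytest.approx(
                standards[cid].max_points)

    def test_energy_only_diet_scores_40(self, standards):
        # nothing consumed: adequacy components 0; moderation components at
        # their best (10 + 10 + 20); trace SFA keeps the ratio defined at 0
        p = IntakeProfile(energy=2000.0,
                          amounts={c: 0.0 for c in COMPONENT_IDS
                                   if c not in ("fatty_acids",
                                                "empty_calories")},
                          sfa_g=0.1)
        score = score_profile(p, standards)
        assert score.total == pytest.approx(40.0)

    def test_density_invariance_under_joint_scaling(self, standards):
        base = perfect_profile(standards)
        for c in (0.5, 2.0, 7.3):
            scaled = IntakeProfile(
                energy=base.energy * c,
                amounts={k: v * c for k, v in base.amounts.items()
                         if k != "fatty_acids"} | {"fatty_acids": 2.5},
                solid_fat_kcal=base.solid_fat_kcal * c)
            assert score_profile(scaled, standards).total == pytest.approx(
                100.0)

    def test_incomplete_standards_rejected(self, standards):
        partial = {k: v for k, v in standards.items() if k != "sodium"}
        with pytest.raises(ValueError):
            score_profile(perfect_profile(standards), partial)

    def test_negative_amount_rejected(self):
        p = IntakeProfile(energy=2000.0, amounts={"total_fruit": -1.0})
        with pytest.raises(InvalidProfileError):
            score_profile(p)


@st.composite
def random_profiles(draw):
    energy = draw(st.floats(500, 5000))
    amounts = {c: draw(st.floats(0, 20))
               for c in COMPONENT_IDS
               if c not in ("fatty_acids", "empty_calories")}
    amounts["fatty_acids"] = draw(st.floats(0, 8))
    return IntakeProfile(
        energy=energy, amounts=amounts,
        solid_fat_kcal=draw(st.floats(0, 800)),
        added_sugar_kcal=draw(st.floats(0, 800)),
        alcohol_g=draw(st.floats(0, 100)))


class TestProperties:
    @settings(max_examples=200, derandomize=True)
    @given(random_profiles())
    def test_score_bounds_and_additivity(self, standards, profile):
        score = score_profile(profile, standards)
        for cid in COMPONENT_IDS:
            assert 0.0 <= score.component_scores[cid] <= \
                standards[cid].max_points + 1e-12
        assert score.total == pytest.approx(
            sum(score.component_scores.values()))
        assert -1e-9 <= score.total <= 100.0 + 1e-9

    @settings(max_examples=50, derandomize=True)
    @given(random_profiles(), st.floats(0.1, 5.0))
    def test_directional_monotonicity(self, standards, profile, bump):
        base = score_profile(profile, standards)
        up = IntakeProfile(
            energy=profile.energy,
            amounts=dict(profile.amounts) | {
                "total_fruit": profile.amounts["total_fruit"] + bump,
                "sodium": profile.amounts["sodium"] + bump},
            solid_fat_kcal=profile.solid_fat_kcal,
            added_sugar_kcal=profile.added_sugar_kcal,
            alcohol_g=profile.alcohol_g)
        bumped = score_profile(up, standards)
        assert bumped.component_scores["total_fruit"] >= \
            base.component_scores["total_fruit"] - 1e-12
        assert bumped.component_scores["sodium"] <= \
            base.component_scores["sodium"] + 1e-12


def test_score_frame_matches_profile_scoring(standards):
    rows = []
    for energy, factor in [(1500.0, 0.5), (2000.0, 1.0), (2600.0, 1.7)]:
        amounts = adequacy_amounts(standards, energy, factor)
        rows.append({"energy": energy, **amounts,
                     "refined_grains": 2.0 * energy / 1000,
                     "sodium": 1.5 * energy / 1000,
                     "fatty_acids": 2.0,
                     "solid_fat_kcal": 0.1 * energy,
                     "added_sugar_kcal": 0.05 * energy,
                     "alcohol_g": 0.0})
    frame = pd.DataFrame(rows)
    scored = score_frame(frame, standards)
    for i, row in frame.iterrows():
        p = IntakeProfile(
            energy=row["energy"],
            amounts={c: row[c] for c in COMPONENT_IDS
                     if c != "empty_calories" and c in row},
            solid_fat_kcal=row["solid_fat_kcal"],
            added_sugar_kcal=row["added_sugar_kcal"])
        assert scored.loc[i, "score_total"] == pytest.approx(
            score_profile(p, standards).total)
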