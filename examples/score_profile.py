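"""Score a single day's intake with HEI-2010.

Builds one intake profile in natural units (cup/oz equivalents per day,
sodium grams, fatty-acid grams, empty-calorie sources), scores it, and prints
the 12 component scores.  Component scores are density based — amounts per
1000 kcal — so the same foods at half the energy score identically.
"""

from dietqual import IntakeProfile, load_standards, score_profile

standards = load_standards()
profile = IntakeProfile(
    energy=2200.0,
    amounts={
        "total_fruit": 1.1, "whole_fruit": 0.6, "total_vegetables": 2.4,
        "greens_beans": 0.3, "whole_grains": 1.4, "dairy": 2.2,
        "total_protein": 6.0, "seafood_plant_protein": 1.2,
        "refined_grains": 5.2, "sodium": 3.4,
    },
    pufa_g=16.0, mufa_g=24.0, sfa_g=22.0,       # ratio (16+24)/22 = 1.8
    solid_fat_kcal=310.0, added_sugar_kcal=210.0, alcohol_g=10.0,
)

score = score_profile(profile, standards)
print("component scores (earned / maximum):")
for cid, pts in score.component_scores.items():
    print(f"  {cid:<22s} {pts:5.2f} / {standards[cid].max_points}")
print(f"total HEI-2010 score: {score.total:.2f} / 100")
print("higher is healthier; moderation components (refined grains, sodium,")
print("empty calories) earn more points the LESS is consumed per 1000 kcal.")
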