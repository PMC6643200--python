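# HEI-2010 component scoring standards (version 2010.1).
#
# Densities are per 1000 kcal except:
#   fatty_acids     — the (PUFA + MUFA) / SFA gram ratio (dimensionless)
#   empty_calories  — percent of total energy
#
# density_at_max earns full points; density_at_zero earns 0 points; scores are
# linear in density between the two anchors and clamped outside them.
version: "2010.1"
components:
  total_fruit:
    max_points: 5
    direction: adequacy
    density_at_max: 0.8
    density_at_zero: 0.0
    units: cup-equiv
  whole_fruit:
    max_points: 5
    direction: adequacy
    density_at_max: 0.4
    density_at_zero: 0.0
    units: cup-equiv
  total_vegetables:
    max_points: 5
    direction: adequacy
    density_at_max: 1.1
    density_at_zero: 0.0
    units: cup-equiv
  greens_beans:
    max_points: 5
    direction: adequacy
    density_at_max: 0.2
    density_at_zero: 0.0
    units: cup-equiv
  whole_grains:
    max_points: 10
    direction: adequacy
    density_at_max: 1.5
    density_at_zero: 0.0
    units: oz-equiv
  dairy:
    max_points: 10
    direction: adequacy
    density_at_max: 1.3
    density_at_zero: 0.0
    units: cup-equiv
  total_protein:
    max_points: 5
    direction: adequacy
    density_at_max: 2.5
    density_at_zero: 0.0
    units: oz-equiv
  seafood_plant_protein:
    max_points: 5
    direction: adequacy
    density_at_max: 0.8
    density_at_zero: 0.0
    units: oz-equiv
  fatty_acids:
    max_points: 10
    direction: ratio
    density_at_max: 2.5
    density_at_zero: 1.2
    units: ratio
  refined_grains:
    max_points: 10
    direction: moderation
    density_at_max: 1.8
    density_at_zero: 4.3
    units: oz-equiv
  sodium:
    max_points: 10
    direction: moderation
    density_at_max: 1.1
    density_at_zero: 2.0
    units: g
  empty_calories:
    max_points: 20
    direction: moderation
    density_at_max: 19.0
    density_at_zero: 50.0
    units: "%energy"
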