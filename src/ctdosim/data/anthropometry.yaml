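# Reference anthropometry for the stylized phantom family.
#
# Heights/masses and organ masses follow the standard reference-individual
# compilations used in computational dosimetry (newborn through adult,
# both sexes). Red bone marrow is carried as fixed site fractions per age
# class (skull / spine / pelvis / other); organ masses in grams.
version: 1
age_years: {newborn: 0.0, 1y: 1.0, 5y: 5.0, 10y: 10.0, 15y: 15.0, adult: 20.0}
head_height_fraction: {newborn: 0.25, 1y: 0.22, 5y: 0.18, 10y: 0.15, 15y: 0.13, adult: 0.12}
rbm_site_fractions:
  newborn: {skull: 0.27, spine: 0.30, pelvis: 0.18, other: 0.25}
  1y:      {skull: 0.24, spine: 0.31, pelvis: 0.20, other: 0.25}
  5y:      {skull: 0.18, spine: 0.33, pelvis: 0.24, other: 0.25}
  10y:     {skull: 0.13, spine: 0.36, pelvis: 0.28, other: 0.23}
  15y:     {skull: 0.10, spine: 0.39, pelvis: 0.32, other: 0.19}
  adult:   {skull: 0.08, spine: 0.42, pelvis: 0.35, other: 0.15}
reference:
  male:
    newborn: {height_cm: 51,  mass_kg: 3.5,
              organs: {brain: 380, red_bone_marrow: 50, colon: 15, thyroid: 1.3,
                       breast: 0.5, lungs: 60, remainder: 2500}}
    1y:      {height_cm: 76,  mass_kg: 10,
              organs: {brain: 950, red_bone_marrow: 150, colon: 45, thyroid: 1.8,
                       breast: 0.8, lungs: 150, remainder: 7200}}
    5y:      {height_cm: 109, mass_kg: 19,
              organs: {brain: 1245, red_bone_marrow: 340, colon: 90, thyroid: 3.4,
                       breast: 1.2, lungs: 300, remainder: 14500}}
    10y:     {height_cm: 138, mass_kg: 32,
              organs: {brain: 1310, red_bone_marrow: 630, colon: 160, thyroid: 7.9,
                       breast: 2.0, lungs: 500, remainder: 25000}}
    15y:     {height_cm: 167, mass_kg: 56,
              organs: {brain: 1420, red_bone_marrow: 1050, colon: 280, thyroid: 12,
                       breast: 2.5, lungs: 900, remainder: 44000}}
    adult:   {height_cm: 176, mass_kg: 73,
              organs: {brain: 1450, red_bone_marrow: 1170, colon: 370, thyroid: 20,
                       breast: 3.0, lungs: 1200, remainder: 58000}}
  female:
    newborn: {height_cm: 51,  mass_kg: 3.4,
              organs: {brain: 380, red_bone_marrow: 50, colon: 15, thyroid: 1.3,
                       breast: 0.5, lungs: 60, remainder: 2450}}
    1y:      {height_cm: 75,  mass_kg: 9.5,
              organs: {brain: 950, red_bone_marrow: 150, colon: 45, thyroid: 1.8,
                       breast: 0.8, lungs: 150, remainder: 6900}}
    5y:      {height_cm: 108, mass_kg: 18,
              organs: {brain: 1245, red_bone_marrow: 340, colon: 90, thyroid: 3.4,
                       breast: 1.5, lungs: 300, remainder: 13800}}
    10y:     {height_cm: 137, mass_kg: 31,
              organs: {brain: 1310, red_bone_marrow: 630, colon: 160, thyroid: 7.9,
                       breast: 5.0, lungs: 500, remainder: 24200}}
    15y:     {height_cm: 161, mass_kg: 53,
              organs: {brain: 1300, red_bone_marrow: 920, colon: 270, thyroid: 12,
                       breast: 250, lungs: 750, remainder: 41500}}
    adult:   {height_cm: 163, mass_kg: 60,
              organs: {brain: 1300, red_bone_marrow: 900, colon: 360, thyroid: 17,
                       breast: 500, lungs: 950, remainder: 47500}}
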