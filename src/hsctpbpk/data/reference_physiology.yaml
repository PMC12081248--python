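# Reference adult physiology (version 1).
#
# Organ volumes and regional blood-flow fractions for a 30-year-old,
# 73 kg / 176 cm adult male, curated from standard reference-human
# compilations (ICRP-type tables as summarized in the PBPK literature,
# e.g. Brown et al. 1997, Valentin 2002). Flow fractions of systemic
# organs sum to exactly 1 so venous return equals cardiac output by
# construction.
version: 1
reference:
  age_years: 30
  weight_kg: 73.0
  height_cm: 176.0
  sex: male
  cardiac_output_L_h: 390.0

# fraction of cardiac output perfusing each systemic organ
# (liver fraction is the hepatic-artery share only; portal inflow
# arrives via gut and spleen)
flow_fractions:
  liver: 0.065
  gut: 0.15
  spleen: 0.03
  kidney: 0.19
  muscle: 0.17
  adipose: 0.05
  skin: 0.05
  brain: 0.12
  heart: 0.04
  bone: 0.05
  rest: 0.085

# organ volumes in L at the reference weight
volumes_L:
  lung: 0.5
  liver: 1.8
  gut: 1.2
  kidney: 0.31
  muscle: 29.0
  adipose: 13.5
  skin: 3.3
  brain: 1.45
  heart: 0.33
  bone: 10.0
  spleen: 0.19
  rest: 2.0
  arterial_blood: 1.7
  venous_blood: 3.9

# allometric exponents for scaling with body weight
# (volumes ~ W^1 except brain; flows via cardiac output ~ W^0.75)
allometry:
  volume_exponent_default: 1.0
  volume_exponent_brain: 0.25
  cardiac_output_exponent: 0.75

# multiplicative adjustments applied for females
sex_adjustments:
  female:
    muscle: 0.85
    adipose: 1.30
    cardiac_output: 0.92

# demographic defaults by (ethnicity, sex): mean weight kg / height cm
demographics:
  European:
    male: {weight: 73.0, height: 176.0}
    female: {weight: 60.0, height: 165.0}
  Japanese:
    male: {weight: 57.0, height: 165.0}
    female: {weight: 57.0, height: 165.0}

# tissue composition used for partition-coefficient calculation:
# fractional water, neutral lipid and phospholipid content
tissue_composition:
  plasma: {water: 0.96, nlipid: 0.0023, plipid: 0.0013}
  lung: {water: 0.81, nlipid: 0.022, plipid: 0.014}
  liver: {water: 0.75, nlipid: 0.014, plipid: 0.024}
  gut: {water: 0.72, nlipid: 0.049, plipid: 0.014}
  kidney: {water: 0.79, nlipid: 0.012, plipid: 0.024}
  muscle: {water: 0.76, nlipid: 0.010, plipid: 0.009}
  adipose: {water: 0.18, nlipid: 0.79, plipid: 0.002}
  skin: {water: 0.72, nlipid: 0.060, plipid: 0.004}
  brain: {water: 0.77, nlipid: 0.050, plipid: 0.057}
  heart: {water: 0.76, nlipid: 0.012, plipid: 0.017}
  bone: {water: 0.44, nlipid: 0.070, plipid: 0.001}
  spleen: {water: 0.78, nlipid: 0.012, plipid: 0.014}
  rest: {water: 0.75, nlipid: 0.040, plipid: 0.010}

# enzyme / transporter registry: baseline expression E0 (umol/L in the
# expressing tissue), first-order pool degradation rate kdeg (1/h) and
# expressing organs with relative weights summing to 1.
# E0 values follow the scale of reported hepatic abundances; kdeg 0.0158 1/h
# corresponds to a ~44 h CYP turnover half-life.
enzymes:
  CYP3A4: {E0: 4.32, kdeg: 0.0158, organs: {liver: 0.9, gut: 0.1}}
  CYP3A5: {E0: 0.04, kdeg: 0.0158, organs: {liver: 1.0}}
  CYP2C9: {E0: 3.84, kdeg: 0.0158, organs: {liver: 1.0}}
  CYP2C19: {E0: 0.76, kdeg: 0.0158, organs: {liver: 1.0}}
  CYP2D6: {E0: 1.56, kdeg: 0.0158, organs: {liver: 1.0}}
  CYP1A2: {E0: 1.80, kdeg: 0.0158, organs: {liver: 1.0}}
  UGT1A1: {E0: 2.00, kdeg: 0.0158, organs: {liver: 0.9, gut: 0.1}}
  UGT1A3: {E0: 1.00, kdeg: 0.0158, organs: {liver: 1.0}}
  UGT1A4: {E0: 1.20, kdeg: 0.0158, organs: {liver: 1.0}}
  GSTA1: {E0: 10.0, kdeg: 0.0158, organs: {liver: 1.0}}
  P-gp: {E0: 1.00, kdeg: 0.0158, organs: {gut: 0.6, liver: 0.3, kidney: 0.1}}
  BCRP: {E0: 0.50, kdeg: 0.0158, organs: {gut: 0.5, liver: 0.5}}
  OATP1B1: {E0: 2.00, kdeg: 0.0158, organs: {liver: 1.0}}
  OATP1B3: {E0: 1.00, kdeg: 0.0158, organs: {liver: 1.0}}
  MRP: {E0: 1.00, kdeg: 0.0158, organs: {liver: 1.0}}
  BSEP: {E0: 0.50, kdeg: 0.0158, organs: {liver: 1.0}}

# phenotype reference concentrations (umol/L) replacing E0 when assigned
phenotypes:
  CYP2C19:
    NM: 0.76
    IM: 0.40
    PM: 0.01
  CYP3A5:
    expresser: 0.68
    non_expresser: 0.04

# per-enzyme ontogeny: piecewise-linear activity multiplier vs age (years).
# Enzymes absent here use 1.0 at all ages. GSTA1 activity per unit liver is
# elevated in young children, consistent with faster weight-normalized
# busulfan clearance in pediatrics.
ontogeny:
  GSTA1: [[0.0, 1.3], [2.0, 1.3], [12.0, 1.0], [120.0, 1.0]]
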