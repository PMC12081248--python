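# Phenytoin: anticonvulsant prophylaxis during conditioning; saturable
# CYP2C9 clearance (Michaelis-Menten) and broad induction of
# drug-metabolizing enzymes (CYP2C9/2C19/3A4, UGT1A4, GSTA1).
# Emax/EC50 pairs are curated to strong-inducer scale; fixtures.
schema_version: 1
name: phenytoin
mw: 252.3
logp: 2.47
fu: 0.10
blood_plasma_ratio: 1.0
absorption:
  model: first_order
  ka: 0.5          # 1/h, slow dissolution-limited absorption
  f_abs: 0.9
pathways:
  - enzyme: CYP2C9
    vmax_specific: 0.2    # umol/min/umol; total Vmax ~ 500 mg/day
    km: 2.0               # umol/L unbound
  - enzyme: CYP2C19
    clint_specific: 2000.0
renal_clearance: 0.0
interactions:
  - kind: induction
    target: CYP3A4
    emax: 3.0      # strong inducer; ~2.5x CYP3A4 at therapeutic exposure
    ec50: 0.8      # umol/L unbound, at the scale of unbound therapeutic exposure
  - kind: induction
    target: CYP2C9
    emax: 2.0
    ec50: 0.8
  - kind: induction
    target: CYP2C19
    emax: 2.0
    ec50: 0.8
  - kind: induction
    target: UGT1A4
    emax: 1.5
    ec50: 0.8
  - kind: induction
    target: GSTA1
    emax: 0.35     # modest GST induction, ~1.15x at steady state
    ec50: 0.8
therapeutic_window:
  metric: Cmin
  lower: 10.0
  upper: 20.0
  unit: ug/mL
  evaluation: trough at steady state (status epilepticus target)
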