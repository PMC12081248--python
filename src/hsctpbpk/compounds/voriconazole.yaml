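# Voriconazole: triazole antifungal; saturable CYP2C19-dominated clearance
# (hence strong CYP2C19-phenotype sensitivity), minor CYP2C9/CYP3A4 routes;
# mechanism-based CYP3A4 inactivator and competitive CYP2C9/2C19 inhibitor.
schema_version: 1
name: voriconazole
mw: 349.3
logp: 1.5
fu: 0.42
blood_plasma_ratio: 1.0
absorption:
  model: first_order
  ka: 1.1
  f_abs: 0.96     # oral bioavailability ~96%
pathways:
  - enzyme: CYP2C19
    vmax_specific: 0.91   # umol/min/umol; ~70% of clearance at low conc
    km: 3.0               # umol/L unbound; source of nonlinear PK
  - enzyme: CYP2C9
    clint_specific: 17400.0
  - enzyme: CYP3A4
    clint_specific: 8000.0
renal_clearance: 0.0
interactions:
  - kind: inhibition
    target: CYP3A4
    type: irreversible      # mechanism-based inactivation
    kinact: 0.07            # 1/h
    KI: 9.0                 # umol/L unbound
  - kind: inhibition
    target: CYP2C9
    type: competitive
    ki: 8.0
  - kind: inhibition
    target: CYP2C19
    type: competitive
    ki: 8.0
therapeutic_window:
  metric: Cmin
  lower: 1.0
  upper: 5.0
  unit: ug/mL
  evaluation: trough at steady state
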