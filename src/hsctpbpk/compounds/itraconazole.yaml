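# Itraconazole: triazole antifungal; CYP3A4 clearance, very low unbound
# fraction, potent competitive CYP3A4 inhibitor, P-gp/BCRP inhibitor.
schema_version: 1
name: itraconazole
mw: 705.6
logp: 5.0
fu: 0.004
blood_plasma_ratio: 1.0
absorption:
  model: first_order
  ka: 0.3
  f_abs: 0.55
pathways:
  - enzyme: CYP3A4
    clint_specific: 14000000.0   # high intrinsic clearance offset by low fu
renal_clearance: 0.0
interactions:
  - kind: inhibition
    target: CYP3A4
    type: competitive
    ki: 0.0013     # umol/L unbound, ~nM-potency
  - kind: inhibition
    target: P-gp
    type: competitive
    ki: 0.1
  - kind: inhibition
    target: BCRP
    type: competitive
    ki: 0.3
therapeutic_window:
  metric: Cmin
  lower: 0.5
  upper: null
  unit: ug/mL
  evaluation: trough at steady state
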