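# Tacrolimus: calcineurin-inhibitor immunosuppressant; CYP3A4 plus
# genotype-dependent CYP3A5 clearance (expressers clear markedly faster);
# weak mechanism-based and competitive CYP3A4 inhibitor.
schema_version: 1
name: tacrolimus
mw: 804.0
logp: 3.3
fu: 0.01
blood_plasma_ratio: 1.0
absorption:
  model: first_order
  ka: 1.0
  f_abs: 0.25
pathways:
  - enzyme: CYP3A4
    clint_specific: 7750000.0
  - enzyme: CYP3A5
    clint_specific: 24000000.0   # sized so *1 expressers gain ~50% clearance
renal_clearance: 0.0
interactions:
  - kind: inhibition
    target: CYP3A4
    type: irreversible
    kinact: 0.05
    KI: 0.5
  - kind: inhibition
    target: CYP3A4
    type: competitive
    ki: 0.1
therapeutic_window:
  metric: Cmin
  lower: 5.0
  upper: 15.0
  unit: ng/mL
  evaluation: trough at steady state
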