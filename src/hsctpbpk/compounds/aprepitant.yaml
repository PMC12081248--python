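# Aprepitant: NK1 antagonist antiemetic; CYP3A4-dominated clearance with
# minor CYP1A2/CYP2C19 routes; weak-to-moderate competitive CYP3A4
# inhibitor and a mild CYP3A4/CYP2C9 inducer.
schema_version: 1
name: aprepitant
mw: 534.4
logp: 4.5
fu: 0.05
blood_plasma_ratio: 1.0
absorption:
  model: first_order
  ka: 0.6
  f_abs: 0.65
pathways:
  - enzyme: CYP3A4
    clint_specific: 129000.0
  - enzyme: CYP1A2
    clint_specific: 35000.0
  - enzyme: CYP2C19
    clint_specific: 41000.0
renal_clearance: 0.0
interactions:
  - kind: inhibition
    target: CYP3A4
    type: competitive
    ki: 0.2
  - kind: induction
    target: CYP3A4
    emax: 0.25
    ec50: 0.3
  - kind: induction
    target: CYP2C9
    emax: 0.3
    ec50: 0.3
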