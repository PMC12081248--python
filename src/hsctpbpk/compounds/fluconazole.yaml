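# Fluconazole: triazole antifungal cleared primarily by renal excretion;
# strong competitive CYP2C19 inhibitor, moderate CYP2C9/CYP3A4 inhibitor.
schema_version: 1
name: fluconazole
mw: 306.3
logp: 0.4
fu: 0.89
blood_plasma_ratio: 1.0
absorption:
  model: first_order
  ka: 1.0
  f_abs: 0.95
pathways:
  - enzyme: CYP3A4
    clint_specific: 250.0       # minor oxidative route
renal_clearance: 0.8            # L/h, dominant route
interactions:
  - kind: inhibition
    target: CYP2C19
    type: competitive
    ki: 2.0
  - kind: inhibition
    target: CYP2C9
    type: competitive
    ki: 8.0
  - kind: inhibition
    target: CYP3A4
    type: competitive
    ki: 10.0
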