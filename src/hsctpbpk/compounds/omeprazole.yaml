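# Omeprazole: proton-pump inhibitor; CYP2C19-dominated high-extraction
# clearance with a CYP3A4 route; mechanism-based CYP2C19 inactivator and
# moderate competitive CYP3A4 inhibitor.
schema_version: 1
name: omeprazole
mw: 345.4
logp: 2.2
fu: 0.05
blood_plasma_ratio: 1.0
absorption:
  model: first_order
  ka: 1.8
  f_abs: 0.9       # first-pass loss emerges from hepatic extraction
pathways:
  - enzyme: CYP2C19
    clint_specific: 7450000.0
  - enzyme: CYP3A4
    clint_specific: 580000.0
renal_clearance: 0.0
interactions:
  - kind: inhibition
    target: CYP2C19
    type: irreversible
    kinact: 0.1     # 1/h
    KI: 2.0         # umol/L unbound
  - kind: inhibition
    target: CYP3A4
    type: competitive
    ki: 40.0
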