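# Letermovir: CMV terminase inhibitor; UGT1A1/1A3 glucuronidation with
# OATP1B-mediated hepatic uptake; inhibits CYP3A4, OATP1B1/3, P-gp, BCRP;
# induces CYP2C9 and CYP2C19.
schema_version: 1
name: letermovir
mw: 572.6
logp: 2.9
fu: 0.012
blood_plasma_ratio: 1.0
absorption:
  model: first_order
  ka: 0.8
  f_abs: 0.94
pathways:
  - enzyme: UGT1A1
    clint_specific: 1260000.0
  - enzyme: UGT1A3
    clint_specific: 810000.0
  - enzyme: OATP1B1
    clint_specific: 407000.0   # uptake-limited hepatic component
renal_clearance: 0.0
interactions:
  - kind: inhibition
    target: CYP3A4
    type: competitive
    ki: 0.08        # umol/L unbound; ~2x midazolam-scale effect
  - kind: inhibition
    target: OATP1B1
    type: competitive
    ki: 0.02
  - kind: inhibition
    target: OATP1B3
    type: competitive
    ki: 0.02
  - kind: inhibition
    target: P-gp
    type: competitive
    ki: 0.3
  - kind: inhibition
    target: BCRP
    type: competitive
    ki: 0.3
  - kind: induction
    target: CYP2C9
    emax: 0.4
    ec50: 0.1
  - kind: induction
    target: CYP2C19
    emax: 0.5
    ec50: 0.1
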